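"""Synthetic hologenome generator.

Emulates the study system end to end so every downstream stage can be tested
without external data: a diploid host population split into two diverged
lineages (Balding-Nichols differentiation), and a dominant, clonally
transmitted bacterial symbiont whose single-nucleotide variants partition by
host lineage.  A ``h_transmission`` knob moves the symbiont from strict
vertical inheritance (mirrored host/symbiont structure) to fully horizontal
acquisition from a pooled cross-lineage source (no mirrored structure), which
is the contrast the co-diversification test is calibrated against.

Everything is driven by one master seed; each output object draws from its
own child stream (fixed labels), so e.g. enlarging the host panel does not
perturb the symbiont draws.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy.stats import binom

from .codon_variants import GeneModel, translate_codon, write_gene_models
from .host_popgen import GenotypeLikelihoods
from .snv_profiles import NUCLEOTIDES, AlleleCountMatrix

__all__ = [
    "HoloSimConfig",
    "HoloSimTruth",
    "SimResult",
    "simulate_host_genotypes",
    "simulate_symbiont_counts",
    "simulate_hologenome",
    "write_hologenome",
]

_STREAM_HOST = 0
_STREAM_GENOME = 1
_STREAM_SYMBIONT = 2

SENSE_CODONS = tuple(
    c
    for c in ("".join(t) for t in itertools.product(NUCLEOTIDES, repeat=3))
    if translate_codon(c) != "*"
)


@dataclass(frozen=True)
class HoloSimConfig:
    """Study conditions for one synthetic hologenome.

    Defaults reflect the emulated system: two lineages of 15 hosts each,
    moderate lineage differentiation (F = 0.1), medium host coverage (20x),
    a small single-contig symbiont genome of contiguous in-frame genes,
    8 vs 16 lineage-diagnostic symbiont SNVs (the southern lineage carries
    the excess variable SNVs), deep symbiont coverage (100x) and strict
    vertical transmission.
    """

    n_hosts_per_cluster: int = 15
    n_host_sites: int = 2000
    fst: float = 0.1
    host_depth_mean: float = 20.0
    host_error: float = 0.01
    sym_gene_lengths: tuple[int, ...] = tuple([50] * 30)  # codons per gene
    n_cluster_snvs: tuple[int, int] = (8, 16)
    sym_depth_mean: float = 100.0
    sym_error: float = 0.001
    within_host_minor_freq: float = 0.3
    h_transmission: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hosts_per_cluster < 2:
            raise ValueError("n_hosts_per_cluster must be >= 2")
        if self.n_host_sites < 1:
            raise ValueError("n_host_sites must be >= 1")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in (0, 1)")
        if self.host_depth_mean <= 0 or self.sym_depth_mean <= 0:
            raise ValueError("depth means must be > 0")
        if not 0.0 <= self.host_error < 0.5:
            raise ValueError("host_error must be in [0, 0.5)")
        if not 0.0 <= self.sym_error < 0.5:
            raise ValueError("sym_error must be in [0, 0.5)")
        if any(g < 2 for g in self.sym_gene_lengths) or not self.sym_gene_lengths:
            raise ValueError("gene lengths must all be >= 2 codons")
        n1, n2 = self.n_cluster_snvs
        if n1 < 0 or n2 < n1:
            raise ValueError(
                "n_cluster_snvs must be non-negative with cluster 2 >= cluster 1"
            )
        if n1 + n2 > sum(self.sym_gene_lengths):
            raise ValueError("more diagnostic SNVs requested than codons available")
        if not 0.0 < self.within_host_minor_freq <= 1.0:
            raise ValueError("within_host_minor_freq must be in (0, 1]")
        if not 0.0 <= self.h_transmission <= 1.0:
            raise ValueError("h_transmission must be in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        n = self.n_hosts_per_cluster
        return [f"c{c}_h{i:02d}" for c in (1, 2) for i in range(1, n + 1)]

    @property
    def genome_length(self) -> int:
        return 3 * sum(self.sym_gene_lengths)


@dataclass
class HoloSimTruth:
    """Ground truth of a simulated hologenome.

    ``cluster_snv_sets`` maps each host cluster to its diagnostic symbiont
    variants as (position, ref_nt, alt_nt) triples; sets are disjoint by
    construction.  ``transmission_source`` is filled in by the symbiont
    simulator ("vertical" or "horizontal"), and ``symbiont_donor`` records
    which cluster's variant pool each host's symbiont actually carries.
    """

    host_cluster: dict[str, int]
    cluster_snv_sets: dict[int, set[tuple[int, str, str]]]
    true_host_allele_freqs: np.ndarray  # 2 x sites
    genes: list[GeneModel]
    genome: str
    transmission_source: dict[str, str] = field(default_factory=dict)
    symbiont_donor: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.genome)
        for cluster, snvs in self.cluster_snv_sets.items():
            for pos, ref, alt in snvs:
                if not 0 <= pos < n:
                    raise ValueError(
                        f"cluster {cluster} SNV position {pos} outside genome"
                    )
                if self.genome[pos] != ref:
                    raise ValueError(f"SNV ref {ref} does not match genome at {pos}")
        if self.cluster_snv_sets.get(1, set()) & self.cluster_snv_sets.get(2, set()):
            raise ValueError("cluster SNV sets must be disjoint")

    def cluster_labels(self, samples: list[str]) -> np.ndarray:
        return np.array([self.host_cluster[s] for s in samples])

    def to_json(self, path) -> None:
        payload = {
            "host_cluster": self.host_cluster,
            "cluster_snv_sets": {
                str(c): sorted([list(t) for t in s])
                for c, s in self.cluster_snv_sets.items()
            },
            "transmission_source": self.transmission_source,
            "symbiont_donor": self.symbiont_donor,
            "true_host_allele_freqs": self.true_host_allele_freqs.tolist(),
            "genome": self.genome,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _stream(seed: int, label: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(label,)))


def _simulate_genome(config: HoloSimConfig):
    """Random single-contig genome of contiguous, in-frame, forward-strand
    genes (ATG start, sense codons throughout) plus the two clusters'
    diagnostic SNV sets, each confined to a distinct codon so no codon ever
    carries two variable positions."""
    rng = _stream(config.seed, _STREAM_GENOME)
    genes: list[GeneModel] = []
    pos = 0
    codons_all: list[str] = []
    for gi, n_codons in enumerate(config.sym_gene_lengths):
        body = rng.choice(len(SENSE_CODONS), size=n_codons - 1)
        codons = ["ATG"] + [SENSE_CODONS[k] for k in body]
        seq = "".join(codons)
        genes.append(
            GeneModel(
                gene_id=f"gene_{gi:03d}",
                contig="sym_contig_1",
                start=pos,
                end=pos + len(seq),
                strand="+",
                seq=seq,
            )
        )
        codons_all.extend(codons)
        pos += len(seq)
    genome = "".join(codons_all)
    n1, n2 = config.n_cluster_snvs
    codon_idx = rng.choice(len(codons_all), size=n1 + n2, replace=False)
    offsets = rng.integers(0, 3, size=n1 + n2)
    snvs: list[tuple[int, str, str]] = []
    for ci, off in zip(codon_idx, offsets):
        p = int(3 * ci + off)
        ref = genome[p]
        alts = [nt for nt in NUCLEOTIDES if nt != ref]
        snvs.append((p, ref, alts[int(rng.integers(0, 3))]))
    return genes, genome, {1: set(snvs[:n1]), 2: set(snvs[n1:])}


def simulate_host_genotypes(
    config: HoloSimConfig,
) -> tuple[GenotypeLikelihoods, HoloSimTruth]:
    """Simulate two diverged host lineages and their genotype likelihoods.

    Per site an ancestral frequency p ~ Uniform(0.05, 0.95) is drawn, the two
    lineage frequencies come from the Balding-Nichols Beta(p(1-F)/F,
    (1-p)(1-F)/F) model, individual diploid genotypes are Binomial(2, p_c),
    read depths are Poisson, and each read supports the carried allele with
    probability 1 - host_error.  Likelihoods are normalized per (individual,
    site); a zero-depth entry is flat and flagged missing.
    """
    rng = _stream(config.seed, _STREAM_HOST)
    s = config.n_host_sites
    n = 2 * config.n_hosts_per_cluster
    samples = config.sample_ids
    clusters = np.repeat([0, 1], config.n_hosts_per_cluster)

    p = rng.uniform(0.05, 0.95, size=s)
    a = p * (1 - config.fst) / config.fst
    b = (1 - p) * (1 - config.fst) / config.fst
    cluster_freqs = rng.beta(a, b, size=(2, s))
    geno = rng.binomial(2, cluster_freqs[clusters])  # N x S
    depth = rng.poisson(config.host_depth_mean, size=(n, s))
    eps = config.host_error
    p_alt_true = eps + (geno / 2.0) * (1 - 2 * eps)
    alt_reads = rng.binomial(depth, p_alt_true)

    g_grid = np.array([0.0, 0.5, 1.0])
    p_alt_model = eps + g_grid[None, None, :] * (1 - 2 * eps)
    logl = binom.logpmf(
        alt_reads[:, :, None], depth[:, :, None], p_alt_model
    )
    logl -= logl.max(axis=2, keepdims=True)
    like = np.exp(logl)
    like /= like.sum(axis=2, keepdims=True)
    missing = depth == 0
    like[missing] = 1.0 / 3.0

    gl = GenotypeLikelihoods(
        individuals=samples,
        sites=np.arange(s),
        likelihoods=like,
        missing=missing,
    )
    genes, genome, snv_sets = _simulate_genome(config)
    truth = HoloSimTruth(
        host_cluster={smp: int(c) + 1 for smp, c in zip(samples, clusters)},
        cluster_snv_sets=snv_sets,
        true_host_allele_freqs=cluster_freqs,
        genes=genes,
        genome=genome,
    )
    return gl, truth


def simulate_symbiont_counts(
    config: HoloSimConfig, truth: HoloSimTruth
) -> AlleleCountMatrix:
    """Simulate the symbiont allele-count matrix given the host truth.

    With probability 1 - h_transmission a host's symbiont population carries
    its own lineage's diagnostic SNV set (vertical transmission); otherwise
    the donor lineage is drawn uniformly from the pooled cross-lineage
    variant pool (horizontal).  At a carried SNV the within-host alternate
    frequency is ``within_host_minor_freq``; read counts per position are
    Multinomial over A/C/G/T at Poisson coverage with the error probability
    spread evenly over the three non-true nucleotides.
    """
    rng = _stream(config.seed, _STREAM_SYMBIONT)
    samples = list(truth.host_cluster)
    n = len(samples)
    length = len(truth.genome)

    nt_index = {nt: k for k, nt in enumerate(NUCLEOTIDES)}
    ref_onehot = np.zeros((length, 4))
    ref_onehot[np.arange(length), [nt_index[nt] for nt in truth.genome]] = 1.0

    freqs = np.repeat(ref_onehot[:, None, :], n, axis=1)  # P x N x 4
    f = config.within_host_minor_freq
    for j, smp in enumerate(samples):
        u = rng.random()
        if u < config.h_transmission:
            donor = int(rng.integers(1, 3))
            truth.transmission_source[smp] = "horizontal"
        else:
            donor = truth.host_cluster[smp]
            truth.transmission_source[smp] = "vertical"
        truth.symbiont_donor[smp] = donor
        for pos, ref, alt in truth.cluster_snv_sets[donor]:
            freqs[pos, j, nt_index[ref]] = 1.0 - f
            freqs[pos, j, nt_index[alt]] = f

    e = config.sym_error
    q = freqs * (1 - e) + (1 - freqs) * (e / 3.0)
    coverage = rng.poisson(config.sym_depth_mean, size=(length, n))
    counts = rng.multinomial(coverage, q)
    return AlleleCountMatrix(
        positions=np.arange(length), samples=samples, counts=counts
    )


class SimResult(NamedTuple):
    genotype_likelihoods: GenotypeLikelihoods
    allele_counts: AlleleCountMatrix
    genes: list[GeneModel]
    truth: HoloSimTruth


def simulate_hologenome(config: HoloSimConfig) -> SimResult:
    """Simulate host and symbiont sides of one hologenome with ground truth."""
    gl, truth = simulate_host_genotypes(config)
    acm = simulate_symbiont_counts(config, truth)
    return SimResult(
        genotype_likelihoods=gl, allele_counts=acm, genes=truth.genes, truth=truth
    )


def write_hologenome(result: SimResult, outdir) -> dict[str, Path]:
    """Write all simulator outputs as plain-text files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "allele_counts": outdir / "symbiont_allele_counts.tsv",
        "gene_map": outdir / "symbiont_genes.tsv",
        "gene_fasta": outdir / "symbiont_genes.fasta",
        "genotype_likelihoods": outdir / "host_genotype_likelihoods.tsv",
        "truth": outdir / "truth.json",
    }
    result.allele_counts.to_tsv(paths["allele_counts"])
    write_gene_models(result.genes, paths["gene_map"], paths["gene_fasta"])
    result.genotype_likelihoods.to_tsv(paths["genotype_likelihoods"])
    result.truth.to_json(paths["truth"])
    return paths
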