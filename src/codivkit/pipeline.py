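"""Pipeline orchestration: configuration, the end-to-end co-diversification
run (simulate -> SNV -> codon -> host structure -> ParaFit -> enrichment),
summary-ratio arithmetic, and the machine-readable run report.

The whole pipeline is a pure function of (config, seed): rerunning with the
same configuration reproduces every output file byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.Align import substitution_matrices

from . import __version__
from .codiv_test import congruence, parafit_global, ward_cluster
from .codon_variants import (
    call_saavs,
    codon_counts_from_alleles,
    gene_pnps,
    read_blosum,
    saav_occurrence,
    saavs_to_frame,
    write_blosum,
)
from .enrichment import OccurrenceTable, enrich
from .host_popgen import (
    SiteFilterConfig,
    filter_sites,
    genotype_covariance_pca,
    host_distance,
)
from .simdata import HoloSimConfig, simulate_hologenome, write_hologenome
from .snv_profiles import SnvFilterConfig, call_snvs, snv_distance

__all__ = [
    "RunConfig",
    "SummaryReport",
    "percent_ratio",
    "run_codiversification",
    "run_pipeline",
    "demo_config",
    "null_demo_config",
]

logger = logging.getLogger(__name__)


def percent_ratio(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * numerator / denominator rounded half-up to ``decimals``."""
    if denominator < 1:
        raise ValueError("denominator must be >= 1")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be between 0 and denominator")
    quantum = Decimal(1).scaleb(-decimals)
    value = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return float(value)


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration with the study-default thresholds.

    ``snv_min_prevalence`` is the genome-wide SNV reporting default (0.90);
    ``codiv_min_prevalence`` is the prevalence used when building the
    co-diversification SNV matrix, where lineage-diagnostic variants are by
    construction carried by only one of the two host clusters (see
    docs/methods.md).  Any override of a default is logged.
    """

    sim: HoloSimConfig = field(default_factory=HoloSimConfig)
    min_variation: float = 0.01
    min_coverage: int = 20
    snv_min_prevalence: float = 0.90
    codiv_min_prevalence: float = 0.45
    snp_p: float = 1e-6
    maf: float = 0.05
    presence: float = 0.50
    n_perm: int = 1000
    q_max: float = 0.05
    sym_distance: str = "presence_absence_jaccard"
    seed: int = 0
    outdir: str = "codivkit_run"

    def snv_filter(self, prevalence: float | None = None) -> SnvFilterConfig:
        return SnvFilterConfig(
            min_variation=self.min_variation,
            min_coverage=self.min_coverage,
            min_prevalence=(
                self.snv_min_prevalence if prevalence is None else prevalence
            ),
        )

    def site_filter(self) -> SiteFilterConfig:
        return SiteFilterConfig(
            snp_p_max=self.snp_p, maf_min=self.maf, presence_min=self.presence
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["sym_gene_lengths"] = list(d["sim"]["sym_gene_lengths"])
        d["sim"]["n_cluster_snvs"] = list(d["sim"]["n_cluster_snvs"])
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sim = dict(data.pop("sim", {}))
        if "sym_gene_lengths" in sim:
            sim["sym_gene_lengths"] = tuple(sim["sym_gene_lengths"])
        if "n_cluster_snvs" in sim:
            sim["n_cluster_snvs"] = tuple(sim["n_cluster_snvs"])
        seed = data.get("seed", 0)
        sim.setdefault("seed", seed)
        defaults = cls(sim=HoloSimConfig(**sim))
        for key, value in data.items():
            if not hasattr(defaults, key):
                raise ValueError(f"unknown config key {key!r}")
            if getattr(defaults, key) != value:
                logger.info("config override: %s = %r", key, value)
        return cls(sim=HoloSimConfig(**sim), **data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _perm_seed(seed: int) -> int:
    """Child seed (< 2**31) for the permutation stream."""
    return int(
        np.random.SeedSequence(seed, spawn_key=(3,)).generate_state(1)[0] % (2**31)
    )


def run_codiversification(
    sim_config: HoloSimConfig,
    snv_cfg: SnvFilterConfig | None = None,
    site_cfg: SiteFilterConfig | None = None,
    n_perm: int = 1000,
    perm_seed: int | None = None,
    sym_distance: str = "presence_absence_jaccard",
) -> dict:
    """Simulate one hologenome and run the co-diversification chain.

    Builds the symbiont SNV distance matrix (presence/absence Jaccard by
    default), the host PC-space distance matrix, and the one-to-one
    host-symbiont association, then runs the global ParaFit permutation test
    and the host/symbiont partition-congruence summary.
    """
    snv_cfg = snv_cfg or SnvFilterConfig(min_prevalence=0.45)
    site_cfg = site_cfg or SiteFilterConfig()
    if perm_seed is None:
        perm_seed = _perm_seed(sim_config.seed)
    sim = simulate_hologenome(sim_config)
    profile = call_snvs(sim.allele_counts, snv_cfg)
    sym_d = snv_distance(profile, sym_distance)
    gl_f = filter_sites(sim.genotype_likelihoods, site_cfg)
    structure = genotype_covariance_pca(gl_f)
    host_d = host_distance(structure)
    assoc = np.eye(len(sim.allele_counts.samples), dtype=int)
    parafit = parafit_global(host_d, sym_d, assoc, n_perm=n_perm, seed=perm_seed)
    truth_labels = sim.truth.cluster_labels(structure.individuals)
    recovery_ari = congruence(truth_labels, structure.cluster_labels)["ari"]
    if profile.n_snvs >= 1:
        ward = ward_cluster(profile.departure_matrix(), profile.samples)
        mirror = congruence(structure.cluster_labels, ward.cluster_labels)
    else:
        ward = None
        mirror = {"ari": float("nan"), "contingency": None}
    return {
        "sim": sim,
        "profile": profile,
        "sym_distance": sym_d,
        "host_structure": structure,
        "host_distance": host_d,
        "parafit": parafit,
        "ward": ward,
        "recovery_ari": recovery_ari,
        "congruence_ari": mirror["ari"],
        "congruence_table": mirror["contingency"],
    }


@dataclass
class SummaryReport:
    """Machine-readable pipeline report; every ratio carries its numerator
    and denominator alongside the rounded percentage."""

    version: str
    config: dict
    config_hash: str
    counts: dict
    ratios: dict
    parafit: dict
    congruence_ari: float
    recovery_ari: float
    pnps_summary: dict
    enrichment_summary: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    def report_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()


def _ratio_entry(numerator: int, denominator: int) -> dict:
    return {
        "numerator": int(numerator),
        "denominator": int(denominator),
        "percent": percent_ratio(numerator, denominator),
    }


def run_pipeline(config: RunConfig) -> SummaryReport:
    """Execute the full pipeline and write every stage's outputs to
    ``config.outdir``; returns the summary report (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    hashed = {k: v for k, v in config.to_dict().items() if k != "outdir"}
    config_hash = hashlib.sha256(
        json.dumps(hashed, sort_keys=True).encode()
    ).hexdigest()

    logger.info("stage simulate: seed=%d", config.sim.seed)
    chain = run_codiversification(
        config.sim,
        snv_cfg=config.snv_filter(prevalence=config.codiv_min_prevalence),
        site_cfg=config.site_filter(),
        n_perm=config.n_perm,
        perm_seed=_perm_seed(config.seed),
        sym_distance=config.sym_distance,
    )
    sim = chain["sim"]
    write_hologenome(sim, outdir / "simulated")

    profile = chain["profile"]
    profile.to_tsv(outdir / "snv_profile.tsv")
    profile.to_wide_tsv(outdir / "snv_matrix.tsv")
    chain["sym_distance"].to_tsv(outdir / "symbiont_distances.tsv")
    chain["host_distance"].to_tsv(outdir / "host_distances.tsv")
    structure = chain["host_structure"]
    structure.coordinates_frame().to_csv(
        outdir / "host_pca.tsv", sep="\t", index_label="individual"
    )
    chain["parafit"].to_json(outdir / "parafit.json")
    if chain["ward"] is not None:
        (outdir / "snv_ward_dendrogram.nwk").write_text(chain["ward"].newick + "\n")

    logger.info("stage codon: %d genes", len(sim.genes))
    blosum_path = outdir / "BLOSUM62.txt"
    write_blosum(substitution_matrices.load("BLOSUM62"), blosum_path)
    blosum = read_blosum(blosum_path)
    table = codon_counts_from_alleles(
        sim.allele_counts, sim.genes, min_variation=config.min_variation
    )
    table.to_tsv(outdir / "codon_variants.tsv")
    pnps = [
        gene_pnps(table, g, min_variation=config.min_variation) for g in sim.genes
    ]
    pnps_frame = pd.DataFrame(
        [
            (r.gene_id, r.n_obs, r.s_obs, r.n_sites, r.s_sites, r.pnps)
            for r in pnps
        ],
        columns=["gene_id", "N_obs", "S_obs", "N_sites", "S_sites", "pnps"],
    )
    pnps_frame.to_csv(outdir / "pnps.tsv", sep="\t", index=False)
    cluster_map = {
        ind: f"cluster{lab}"
        for ind, lab in zip(structure.individuals, structure.cluster_labels)
    }
    saavs = call_saavs(
        table, blosum, host_clusters=cluster_map, min_variation=config.min_variation
    )
    saavs_to_frame(saavs).to_csv(outdir / "saavs.tsv", sep="\t", index=False)

    logger.info("stage enrich: %d SAAVs", len(saavs))
    if saavs:
        occurrence = saav_occurrence(table, saavs, min_variation=config.min_variation)
        groups = pd.Series(
            {s: cluster_map[s] for s in occurrence.columns}, name="group"
        )
        enrichment = enrich(
            OccurrenceTable(occurrence=occurrence, groups=groups), q_max=config.q_max
        )
        enrichment.to_csv(outdir / "saav_enrichment.tsv", sep="\t")
        n_enriched = int(enrichment["enriched"].sum())
        n_features = len(enrichment)
    else:
        n_enriched = n_features = 0

    n_samples = len(sim.allele_counts.samples)
    labels = structure.cluster_labels
    pos_selected = int(sum(1 for r in pnps if np.isfinite(r.pnps) and r.pnps > 1))
    counts = {
        "hosts": n_samples,
        "host_sites_simulated": sim.genotype_likelihoods.n_sites,
        "host_sites_retained": len(structure.sites),
        "symbiont_genome_length": len(sim.truth.genome),
        "snvs_retained": profile.n_snvs,
        "genes": len(sim.genes),
        "saavs": len(saavs),
        "enrichment_features": n_features,
        "enriched_features": n_enriched,
        "genes_pnps_above_1": pos_selected,
    }
    ratios = {
        "host_sites_retained": _ratio_entry(
            len(structure.sites), sim.genotype_likelihoods.n_sites
        ),
        "cluster1_membership": _ratio_entry(int((labels == 1).sum()), n_samples),
        "snvs_retained_of_genome": _ratio_entry(
            profile.n_snvs, len(sim.truth.genome)
        ),
    }
    parafit = chain["parafit"]
    report = SummaryReport(
        version=__version__,
        config=config.to_dict(),
        config_hash=config_hash,
        counts=counts,
        ratios=ratios,
        parafit={
            "statistic": parafit.statistic,
            "p_value": parafit.p_value,
            "n_permutations": parafit.n_permutations,
            "seed": parafit.seed,
            "host_cailliez_constant": parafit.host_correction,
            "sym_cailliez_constant": parafit.sym_correction,
        },
        congruence_ari=float(chain["congruence_ari"]),
        recovery_ari=float(chain["recovery_ari"]),
        pnps_summary={
            "defined": int(sum(1 for r in pnps if np.isfinite(r.pnps))),
            "undefined": int(sum(1 for r in pnps if np.isnan(r.pnps))),
            "infinite": int(
                sum(1 for r in pnps if np.isinf(r.pnps))
            ),
        },
        enrichment_summary={"features": n_features, "enriched": n_enriched},
    )
    report.to_json(outdir / "report.json")
    return report


def demo_config(outdir: str = "codivkit_demo", seed: int = 7) -> RunConfig:
    """The bundled co-diversifying demo: strict vertical transmission, two
    15-host lineages, 8 vs 16 diagnostic SNVs at 100x."""
    return RunConfig(sim=HoloSimConfig(seed=seed), seed=seed, outdir=outdir)


def null_demo_config(outdir: str = "codivkit_null_demo", seed: int = 0) -> RunConfig:
    """The bundled null demo: fully horizontal transmission (no
    co-diversification signal)."""
    return RunConfig(
        sim=HoloSimConfig(h_transmission=1.0, seed=seed), seed=seed, outdir=outdir
    )
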