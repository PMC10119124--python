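"""Codon-level variation: single-codon-variant (SCV) tables reconstructed
from per-position allele counts, Nei-Gojobori style pN/pS per gene, and
single-amino-acid-variant (SAAV) calling with BLOSUM62 interchangeability
scores.

Without read-level data a codon's variant composition cannot be observed
directly; codons are reconstructed from positional counts under an
independence approximation that is exact only when at most one of the three
codon positions is variable.  Codons with two or more variable positions are
flagged ambiguous and excluded from downstream statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .snv_profiles import NUCLEOTIDES, AlleleCountMatrix, _departure_arrays

__all__ = [
    "GeneModel",
    "CodonVariantTable",
    "PnPsResult",
    "SaavRecord",
    "codon_counts_from_alleles",
    "ng_site_counts",
    "gene_pnps",
    "call_saavs",
    "read_blosum",
    "write_blosum",
    "read_gene_models",
    "write_gene_models",
    "translate_codon",
]

logger = logging.getLogger(__name__)

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_START_CODONS = ("ATG", "GTG", "TTG")  # bacterial starts accepted
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@lru_cache(maxsize=None)
def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon; '*' for a stop codon."""
    codon = codon.upper()
    if codon in _STANDARD_TABLE.stop_codons:
        return "*"
    return _STANDARD_TABLE.forward_table[codon]


@dataclass
class GeneModel:
    """A protein-coding gene: 0-based half-open coordinates on a contig plus
    its (forward-strand) coding sequence."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = str(self.seq).upper()
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.end - self.start != len(self.seq):
            raise ValueError("coordinates do not match sequence length")
        if len(self.seq) % 3 != 0:
            raise ValueError(f"gene {self.gene_id}: length not divisible by 3")
        if len(self.seq) < 6:
            raise ValueError(f"gene {self.gene_id}: shorter than 6 nt")
        protein = str(Seq(self.seq).translate(table=1))
        if "*" in protein[:-1]:
            raise ValueError(f"gene {self.gene_id}: internal stop codon")

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3

    def codons(self) -> list[str]:
        return [self.seq[i : i + 3] for i in range(0, len(self.seq), 3)]


def write_gene_models(genes: list[GeneModel], map_path, fasta_path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.contig, g.start, g.end, g.strand) for g in genes],
        columns=["gene_id", "contig", "start", "end", "strand"],
    ).to_csv(map_path, sep="\t", index=False)
    records = [
        SeqRecord(Seq(g.seq), id=g.gene_id, description="") for g in genes
    ]
    SeqIO.write(records, fasta_path, "fasta")


def read_gene_models(map_path, fasta_path) -> list[GeneModel]:
    table = pd.read_csv(map_path, sep="\t")
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(fasta_path, "fasta")}
    genes = []
    for row in table.itertuples(index=False):
        if row.gene_id not in seqs:
            raise ValueError(f"gene {row.gene_id} missing from FASTA")
        genes.append(
            GeneModel(
                gene_id=str(row.gene_id),
                contig=str(row.contig),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                seq=seqs[row.gene_id],
            )
        )
    return genes


def read_blosum(path):
    """Read a substitution matrix in NCBI flat format (e.g. BLOSUM62)."""
    return substitution_matrices.read(str(path))


def write_blosum(matrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(str(matrix))


@dataclass
class CodonVariantTable:
    """Reconstructed codon counts per (gene, codon_index, sample).

    ``records`` is a long table with columns gene_id, codon_index, sample,
    codon, count, coverage; within one (gene, codon, sample) group the codon
    counts sum to the codon coverage (the minimum of the three positional
    coverages).  ``ambiguous`` lists the (gene, codon_index, sample) triples
    that were excluded for having >= 2 variable positions.
    """

    records: pd.DataFrame
    ambiguous: pd.DataFrame

    def pooled_counts(self) -> pd.DataFrame:
        """Codon counts summed over samples per (gene, codon_index, codon)."""
        return (
            self.records.groupby(["gene_id", "codon_index", "codon"], as_index=False)[
                "count"
            ].sum()
        )

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def _apportion(freqs: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``freqs`` (largest
    remainder; ties to the lowest index)."""
    raw = freqs * total
    base = np.floor(raw).astype(np.int64)
    short = total - base.sum()
    if short > 0:
        remainder = raw - base
        order = np.lexsort((np.arange(len(freqs)), -remainder))
        base[order[:short]] += 1
    return base


def codon_counts_from_alleles(
    acm: AlleleCountMatrix,
    genes: list[GeneModel],
    min_variation: float = 0.01,
) -> CodonVariantTable:
    """Reconstruct per-codon counts from positional allele counts.

    Codon coverage is the minimum positional coverage across the codon's
    three positions.  A position is treated as variable when its departure
    from consensus exceeds ``min_variation``.  With zero variable positions
    the codon is the consensus codon; with exactly one, counts at the
    variable position are apportioned over codons; with two or more the codon
    is flagged ambiguous and excluded.
    """
    pos_index = {int(p): i for i, p in enumerate(acm.positions)}
    consensus, _, d, coverage = _departure_arrays(acm.counts)
    variable = np.nan_to_num(d, nan=0.0) > min_variation
    rows: list[tuple] = []
    ambiguous: list[tuple] = []
    n_samples = len(acm.samples)
    for gene in genes:
        span = range(gene.start, gene.end)
        try:
            idx = np.array([pos_index[p] for p in span])
        except KeyError as exc:
            raise ValueError(
                f"gene {gene.gene_id} position {exc} outside allele count matrix"
            ) from None
        sub_counts = acm.counts[idx]  # L x S x 4
        sub_cons = consensus[idx]
        sub_var = variable[idx]
        sub_cov = coverage[idx]
        if gene.strand == "-":
            sub_counts = sub_counts[::-1][:, :, ::-1]
            sub_cons = 3 - sub_cons[::-1]
            sub_var = sub_var[::-1]
            sub_cov = sub_cov[::-1]
        n_codons = len(span) // 3
        for ci in range(n_codons):
            sl = slice(3 * ci, 3 * ci + 3)
            cod_cov = sub_cov[sl].min(axis=0)  # per sample
            n_var = sub_var[sl].sum(axis=0)
            cons_nt = sub_cons[sl]  # 3 x S
            for j in range(n_samples):
                cov = int(cod_cov[j])
                if cov == 0:
                    continue
                if n_var[j] >= 2:
                    ambiguous.append((gene.gene_id, ci, acm.samples[j]))
                    continue
                cons_codon = "".join(NUCLEOTIDES[k] for k in cons_nt[:, j])
                if n_var[j] == 0:
                    rows.append(
                        (gene.gene_id, ci, acm.samples[j], cons_codon, cov, cov)
                    )
                    continue
                vpos = int(np.nonzero(sub_var[sl, j])[0][0])
                nt_counts = sub_counts[sl][vpos, j].astype(float)
                alloc = _apportion(nt_counts / nt_counts.sum(), cov)
                for k in range(4):
                    if alloc[k] == 0:
                        continue
                    codon = (
                        cons_codon[:vpos] + NUCLEOTIDES[k] + cons_codon[vpos + 1 :]
                    )
                    rows.append(
                        (gene.gene_id, ci, acm.samples[j], codon, int(alloc[k]), cov)
                    )
    if ambiguous:
        logger.info(
            "excluded %d (gene, codon, sample) entries with >=2 variable positions",
            len(ambiguous),
        )
    records = pd.DataFrame(
        rows,
        columns=["gene_id", "codon_index", "sample", "codon", "count", "coverage"],
    )
    amb = pd.DataFrame(ambiguous, columns=["gene_id", "codon_index", "sample"])
    return CodonVariantTable(records=records, ambiguous=amb)


@lru_cache(maxsize=None)
def ng_site_counts(codon: str) -> tuple[float, float]:
    """Nei-Gojobori synonymous / non-synonymous site counts for one codon.

    For each of the three positions, the fraction of the three possible
    single-nucleotide changes that preserve the amino acid is summed into the
    synonymous site count; changes to stop codons count as non-synonymous.
    syn + nonsyn = 3 exactly.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(nt not in NUCLEOTIDES for nt in codon):
        raise ValueError(f"invalid codon {codon!r}")
    aa = translate_codon(codon)
    if aa == "*":
        raise ValueError("site counts undefined for stop codons")
    syn = 0.0
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if translate_codon(mutant) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@dataclass
class PnPsResult:
    """Per-gene polymorphism counts and the site-normalized pN/pS ratio.

    ``pnps`` is NaN when no polymorphisms were observed at all and +inf when
    non-synonymous polymorphisms occur without any synonymous ones.
    """

    gene_id: str
    n_obs: int
    s_obs: int
    n_sites: float
    s_sites: float
    pnps: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.pnps)


def _variant_codons(group: pd.DataFrame, min_variation: float):
    """Consensus codon and variant codons (freq > min_variation) from a
    codon-count table for a single (gene, codon_index)."""
    counts = group.groupby("codon")["count"].sum().sort_index()
    total = counts.sum()
    consensus = counts.idxmax()  # ties -> lexicographically first codon
    variants = [
        c
        for c, k in counts.items()
        if c != consensus and k / total > min_variation
    ]
    return consensus, variants


def gene_pnps(
    table: CodonVariantTable,
    gene: GeneModel,
    sample_scope: str = "pooled",
    min_variation: float = 0.01,
) -> PnPsResult:
    """pN/pS for one gene from its reconstructed codon counts.

    Every non-consensus codon exceeding ``min_variation`` frequency counts as
    one polymorphism, classified synonymous iff it encodes the consensus
    codon's amino acid.  Expected site counts follow Nei-Gojobori accounting
    over the consensus codons, so N_sites + S_sites = 3 * n_codons.

    ``sample_scope='pooled'`` (default) pools counts across samples before
    calling variants; ``'per_sample'`` calls variants within each sample and
    sums the polymorphism counts over samples.
    """
    if sample_scope not in ("pooled", "per_sample"):
        raise ValueError(f"unknown sample_scope {sample_scope!r}")
    sub = table.records[table.records["gene_id"] == gene.gene_id]
    if sub.empty:
        raise ValueError(f"gene {gene.gene_id} has no unambiguous codons")
    n_obs = s_obs = 0
    n_sites = s_sites = 0.0
    for ci, group in sub.groupby("codon_index"):
        consensus, _ = _variant_codons(group, min_variation)
        syn, nonsyn = ng_site_counts(consensus)
        s_sites += syn
        n_sites += nonsyn
        if sample_scope == "pooled":
            scopes = [group]
        else:
            scopes = [g for _, g in group.groupby("sample")]
        seen_n: set[str] = set()
        seen_s: set[str] = set()
        for scope in scopes:
            cons, variants = _variant_codons(scope, min_variation)
            cons_aa = translate_codon(cons)
            for v in variants:
                if translate_codon(v) == cons_aa:
                    seen_s.add(v)
                else:
                    seen_n.add(v)
        n_obs += len(seen_n)
        s_obs += len(seen_s)
    if n_obs == 0 and s_obs == 0:
        pnps = float("nan")
    elif s_obs == 0:
        pnps = float("inf")
    else:
        pnps = (n_obs / n_sites) / (s_obs / s_sites)
    return PnPsResult(
        gene_id=gene.gene_id,
        n_obs=n_obs,
        s_obs=s_obs,
        n_sites=n_sites,
        s_sites=s_sites,
        pnps=pnps,
    )


@dataclass
class SaavRecord:
    """A single amino acid variant with its BLOSUM62 interchangeability
    score and per-host-cluster prevalence."""

    gene_id: str
    codon_index: int
    consensus_aa: str
    competing_aa: str
    departure: float
    blosum62: float
    prevalence: dict[str, float]


def _aa_frequencies(group: pd.DataFrame) -> pd.Series:
    counts: dict[str, int] = {}
    for codon, k in zip(group["codon"], group["count"]):
        aa = translate_codon(codon)
        counts[aa] = counts.get(aa, 0) + int(k)
    freq = pd.Series(counts).sort_index()
    return freq / freq.sum()


def call_saavs(
    table: CodonVariantTable,
    blosum,
    host_clusters: dict[str, object] | None = None,
    min_variation: float = 0.01,
) -> list[SaavRecord]:
    """Call SAAVs from reconstructed codon counts.

    A SAAV is emitted at a codon where a non-consensus amino acid exceeds
    ``min_variation`` frequency in the pooled counts.  Prevalence per host
    cluster is the fraction of that cluster's samples in which the competing
    amino acid individually exceeds the threshold.  The BLOSUM62 score of the
    (consensus, competing) pair is taken verbatim from the supplied matrix.
    """
    saavs: list[SaavRecord] = []
    clusters = host_clusters or {}
    cluster_names = sorted({str(c) for c in clusters.values()})
    for (gene_id, ci), group in table.records.groupby(["gene_id", "codon_index"]):
        freqs = _aa_frequencies(group).sort_index()
        consensus_aa = freqs.idxmax()
        competitors = freqs.drop(consensus_aa)
        competitors = competitors[competitors > min_variation]
        if competitors.empty:
            continue
        per_sample_pass: dict[str, set[str]] = {}
        for sample, sg in group.groupby("sample"):
            f = _aa_frequencies(sg)
            per_sample_pass[sample] = {
                a for a, x in f.items() if a != consensus_aa and x > min_variation
            }
        for comp_aa, comp_freq in competitors.items():
            try:
                score = float(blosum[consensus_aa][comp_aa])
            except (KeyError, IndexError):
                raise ValueError(
                    f"pair ({consensus_aa}, {comp_aa}) missing from the "
                    "substitution matrix"
                ) from None
            prevalence = {}
            for cname in cluster_names:
                members = [s for s, c in clusters.items() if str(c) == cname]
                if members:
                    hits = sum(
                        comp_aa in per_sample_pass.get(s, set()) for s in members
                    )
                    prevalence[cname] = hits / len(members)
            saavs.append(
                SaavRecord(
                    gene_id=gene_id,
                    codon_index=int(ci),
                    consensus_aa=str(consensus_aa),
                    competing_aa=str(comp_aa),
                    departure=float(1.0 - freqs[consensus_aa]),
                    blosum62=score,
                    prevalence=prevalence,
                )
            )
    return saavs


def saav_occurrence(
    table: CodonVariantTable,
    saavs: list[SaavRecord],
    min_variation: float = 0.01,
) -> pd.DataFrame:
    """0/1 occurrence of each SAAV per sample (features x samples).

    A SAAV occurs in a sample when the competing amino acid's frequency in
    that sample exceeds ``min_variation``.
    """
    samples = sorted(table.records["sample"].unique())
    keys = {(s.gene_id, s.codon_index) for s in saavs}
    rec = table.records
    mask = pd.MultiIndex.from_frame(rec[["gene_id", "codon_index"]]).isin(keys)
    sub = rec[mask].copy()
    sub["aa"] = sub["codon"].map(translate_codon)
    aa_counts = sub.groupby(["gene_id", "codon_index", "sample", "aa"])["count"].sum()
    totals = aa_counts.groupby(level=[0, 1, 2]).transform("sum")
    freq = aa_counts / totals
    rows = {}
    for s in saavs:
        name = f"{s.gene_id}:codon{s.codon_index}:{s.consensus_aa}>{s.competing_aa}"
        row = []
        for smp in samples:
            key = (s.gene_id, s.codon_index, smp, s.competing_aa)
            f = freq.get(key, 0.0)
            row.append(int(f > min_variation))
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=samples)


def saavs_to_frame(saavs: list[SaavRecord]) -> pd.DataFrame:
    rows = []
    for s in saavs:
        row = {
            "gene_id": s.gene_id,
            "codon_index": s.codon_index,
            "consensus_aa": s.consensus_aa,
            "competing_aa": s.competing_aa,
            "departure": s.departure,
            "blosum62": s.blosum62,
        }
        for k, v in s.prevalence.items():
            row[f"prevalence_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
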