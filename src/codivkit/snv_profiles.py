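"""Per-position nucleotide variability (departure from consensus) and SNV
reporting filters for a symbiont population profiled across host metagenomes.

A position is reported as an SNV when, in a large enough fraction of samples,
it is covered adequately and more than ``min_variation`` of the recruited
reads differ from the per-sample consensus nucleotide.  Defaults follow
common metagenome practice: >1% within-sample variation, >=20x coverage, in
>=90% of samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .codiv_test import DistanceMatrix

__all__ = [
    "NUCLEOTIDES",
    "AlleleCountMatrix",
    "SnvFilterConfig",
    "SnvProfile",
    "departure_from_consensus",
    "call_snvs",
    "snv_distance",
]

logger = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "C", "G", "T")


@dataclass
class AlleleCountMatrix:
    """Per-position, per-sample nucleotide read counts.

    ``counts`` has shape (positions, samples, 4) in fixed A, C, G, T order;
    genome coordinates are 0-based.
    """

    positions: np.ndarray
    samples: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.positions), len(self.samples), 4):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.positions)} positions x {len(self.samples)} samples x 4"
            )
        if (self.counts < 0).any():
            raise ValueError("negative allele counts")
        if len(self.positions) > 1 and not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique")

    @property
    def coverage(self) -> np.ndarray:
        """positions x samples total read counts."""
        return self.counts.sum(axis=2)

    def to_tsv(self, path) -> None:
        pos = np.repeat(self.positions, len(self.samples))
        smp = np.tile(np.asarray(self.samples, dtype=object), len(self.positions))
        flat = self.counts.reshape(-1, 4)
        df = pd.DataFrame({"pos": pos, "sample": smp})
        for k, nt in enumerate(NUCLEOTIDES):
            df[nt] = flat[:, k]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AlleleCountMatrix":
        df = pd.read_csv(path, sep="\t")
        positions = np.sort(df["pos"].unique())
        samples = list(dict.fromkeys(df["sample"].astype(str)))
        pos_idx = {p: i for i, p in enumerate(positions)}
        smp_idx = {s: j for j, s in enumerate(samples)}
        counts = np.zeros((len(positions), len(samples), 4), dtype=np.int64)
        i = df["pos"].map(pos_idx).to_numpy()
        j = df["sample"].astype(str).map(smp_idx).to_numpy()
        counts[i, j] = df[list(NUCLEOTIDES)].to_numpy(np.int64)
        return cls(positions=positions, samples=samples, counts=counts)


@dataclass(frozen=True)
class SnvFilterConfig:
    """SNV reporting thresholds (defaults: >1% variation, 20x, 90% of samples)."""

    min_variation: float = 0.01
    min_coverage: int = 20
    min_prevalence: float = 0.90

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_variation < 1.0:
            raise ValueError("min_variation must be in [0, 1)")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not 0.0 < self.min_prevalence <= 1.0:
            raise ValueError("min_prevalence must be in (0, 1]")


def _departure_arrays(counts: np.ndarray):
    """Vectorized consensus / competing / departure over a (..., 4) array.

    Ties are broken by the fixed A < C < G < T order (argmax returns the
    first maximum).  Zero-coverage entries get departure NaN.
    """
    counts = np.asarray(counts)
    coverage = counts.sum(axis=-1)
    consensus = counts.argmax(axis=-1)
    masked = counts.copy().astype(np.int64)
    np.put_along_axis(masked, consensus[..., None], -1, axis=-1)
    competing = masked.argmax(axis=-1)
    top = np.take_along_axis(counts, consensus[..., None], axis=-1)[..., 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - top / coverage
    d = np.where(coverage > 0, d, np.nan)
    return consensus, competing, d, coverage


def departure_from_consensus(counts4):
    """Consensus nucleotide, competing nucleotide, and departure for one
    position in one sample.

    departure = 1 - consensus_count / coverage; ties at the maximum (and at
    the second-largest count) are resolved in A < C < G < T order.  Raises on
    zero coverage (callers mark uncovered entries as undefined instead).
    """
    counts4 = np.asarray(counts4)
    if counts4.shape != (4,):
        raise ValueError("expected 4 nucleotide counts")
    if (counts4 < 0).any():
        raise ValueError("negative counts")
    if counts4.sum() < 1:
        raise ValueError("departure undefined at zero coverage")
    cons, comp, d, _ = _departure_arrays(counts4)
    return NUCLEOTIDES[int(cons)], NUCLEOTIDES[int(comp)], float(d)


@dataclass
class SnvProfile:
    """Filtered positions x samples variability profile.

    ``departure`` is NaN where a sample had zero coverage; ``present`` marks
    (position, sample) pairs that individually pass the coverage gate and the
    variation threshold.
    """

    positions: np.ndarray
    samples: list[str]
    departure: np.ndarray
    consensus: np.ndarray  # integer codes into NUCLEOTIDES
    competing: np.ndarray
    coverage: np.ndarray
    present: np.ndarray
    config: SnvFilterConfig

    @property
    def n_snvs(self) -> int:
        return len(self.positions)

    def sample_snv_sets(self) -> dict[str, set[int]]:
        return {
            s: set(self.positions[self.present[:, j]].tolist())
            for j, s in enumerate(self.samples)
        }

    def departure_matrix(self) -> np.ndarray:
        """Samples x positions departure values with below-gate or uncovered
        entries imputed as 0 (the clustering/distance substrate)."""
        gated = np.where(
            self.coverage >= self.config.min_coverage,
            np.nan_to_num(self.departure, nan=0.0),
            0.0,
        )
        return gated.T

    def to_tsv(self, path) -> None:
        rows = []
        for i, pos in enumerate(self.positions):
            for j, s in enumerate(self.samples):
                rows.append(
                    (
                        pos,
                        s,
                        self.coverage[i, j],
                        NUCLEOTIDES[self.consensus[i, j]],
                        NUCLEOTIDES[self.competing[i, j]],
                        self.departure[i, j],
                        bool(self.present[i, j]),
                    )
                )
        pd.DataFrame(
            rows,
            columns=[
                "pos",
                "sample",
                "coverage",
                "consensus",
                "competing",
                "departure",
                "present",
            ],
        ).to_csv(path, sep="\t", index=False)

    def to_wide_tsv(self, path) -> None:
        """Samples x SNV departure matrix (the heatmap-style layout)."""
        pd.DataFrame(
            self.departure.T,
            index=self.samples,
            columns=[f"pos{p}" for p in self.positions],
        ).to_csv(path, sep="\t", index_label="sample")


def call_snvs(acm: AlleleCountMatrix, cfg: SnvFilterConfig | None = None) -> SnvProfile:
    """Apply the SNV reporting filters to an allele-count matrix.

    A position is retained iff the fraction of samples in which
    coverage >= min_coverage AND departure > min_variation is at least
    min_prevalence.  The per-sample gates are applied first, prevalence last.
    """
    cfg = cfg or SnvFilterConfig()
    if len(acm.samples) == 0:
        raise ValueError("allele count matrix has no samples")
    consensus, competing, d, coverage = _departure_arrays(acm.counts)
    cov_ok = coverage >= cfg.min_coverage
    var_ok = np.nan_to_num(d, nan=0.0) > cfg.min_variation
    passing = cov_ok & var_ok
    prevalence = passing.mean(axis=1)
    keep = prevalence >= cfg.min_prevalence
    if not keep.any():
        logger.warning(
            "no positions passed SNV filters (min_variation=%g, min_coverage=%d, "
            "min_prevalence=%g)",
            cfg.min_variation,
            cfg.min_coverage,
            cfg.min_prevalence,
        )
    return SnvProfile(
        positions=acm.positions[keep],
        samples=list(acm.samples),
        departure=d[keep],
        consensus=consensus[keep],
        competing=competing[keep],
        coverage=coverage[keep],
        present=passing[keep],
        config=cfg,
    )


def snv_distance(profile: SnvProfile, mode: str = "presence_absence_jaccard") -> DistanceMatrix:
    """Pairwise sample distances from an SNV profile.

    ``presence_absence_jaccard``: 1 - |intersection| / |union| of the samples'
    SNV sets (a pair with two empty sets is at distance 0).
    ``euclidean_on_d``: Euclidean distance between departure vectors over the
    retained positions, with departures that are undefined or below the
    coverage gate imputed as 0.
    """
    if len(profile.samples) < 2:
        raise ValueError("need at least 2 samples for distances")
    if mode == "presence_absence_jaccard":
        x = profile.present.astype(np.int64)  # positions x samples
        inter = x.T @ x
        sizes = x.sum(axis=0)
        union = sizes[:, None] + sizes[None, :] - inter
        with np.errstate(divide="ignore", invalid="ignore"):
            dist = 1.0 - inter / union
        dist[union == 0] = 0.0
        np.fill_diagonal(dist, 0.0)
    elif mode == "euclidean_on_d":
        gated = np.where(
            profile.coverage >= profile.config.min_coverage,
            np.nan_to_num(profile.departure, nan=0.0),
            0.0,
        )
        n_imputed = int(
            (profile.coverage < profile.config.min_coverage).sum()
        )
        if n_imputed:
            logger.info(
                "imputed %d below-coverage departures as 0 for euclidean distances",
                n_imputed,
            )
        dist = squareform(pdist(gated.T, metric="euclidean"))
    else:
        raise ValueError(f"unknown snv distance mode {mode!r}")
    return DistanceMatrix(labels=list(profile.samples), values=dist)
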