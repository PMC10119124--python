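"""Host population structure from genotype likelihoods.

Works on per-individual, per-site likelihoods of the three diploid genotypes
(the natural substrate for low/medium coverage data, where hard genotype
calls are unreliable): maximum-likelihood allele frequencies under
Hardy-Weinberg, a likelihood-ratio SNP test, the standard presence/MAF/SNP-p
site filters, a one-pass posterior-dosage covariance PCA, and a two-cluster
assignment of individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2

from .codiv_test import DistanceMatrix

__all__ = [
    "GenotypeLikelihoods",
    "SiteFilterConfig",
    "HostStructure",
    "ml_allele_frequency",
    "snp_lrt",
    "filter_sites",
    "genotype_covariance_pca",
    "host_distance",
]

logger = logging.getLogger(__name__)

_EM_TOL = 1e-8
_EM_MAX_ITER = 500


@dataclass
class GenotypeLikelihoods:
    """individuals x sites x 3 genotype likelihoods (homRef, het, homAlt),
    normalized per (individual, site); ``missing`` marks entries with no
    reads (their likelihoods are flat and carry no information)."""

    individuals: list[str]
    sites: np.ndarray
    likelihoods: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=np.int64)
        self.likelihoods = np.asarray(self.likelihoods, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        n, s = len(self.individuals), len(self.sites)
        if self.likelihoods.shape != (n, s, 3):
            raise ValueError(
                f"likelihood shape {self.likelihoods.shape} does not match "
                f"{n} individuals x {s} sites x 3"
            )
        if self.missing.shape != (n, s):
            raise ValueError("missing mask shape mismatch")
        if (self.likelihoods < 0).any():
            raise ValueError("negative likelihoods")
        total = self.likelihoods.sum(axis=2)
        if not ((total > 0) | self.missing).all():
            raise ValueError("all-zero likelihoods at a non-missing entry")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset_sites(self, keep: np.ndarray) -> "GenotypeLikelihoods":
        return GenotypeLikelihoods(
            individuals=list(self.individuals),
            sites=self.sites[keep],
            likelihoods=self.likelihoods[:, keep],
            missing=self.missing[:, keep],
        )

    def to_tsv(self, path) -> None:
        ind = np.repeat(np.asarray(self.individuals, dtype=object), self.n_sites)
        site = np.tile(self.sites, self.n_individuals)
        flat = self.likelihoods.reshape(-1, 3)
        pd.DataFrame(
            {
                "individual": ind,
                "site": site,
                "L_AA": flat[:, 0],
                "L_Aa": flat[:, 1],
                "L_aa": flat[:, 2],
                "missing": self.missing.reshape(-1).astype(int),
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenotypeLikelihoods":
        df = pd.read_csv(path, sep="\t")
        individuals = list(dict.fromkeys(df["individual"].astype(str)))
        sites = np.sort(df["site"].unique())
        i = df["individual"].astype(str).map(
            {s: k for k, s in enumerate(individuals)}
        ).to_numpy()
        j = df["site"].map({p: k for k, p in enumerate(sites)}).to_numpy()
        like = np.full((len(individuals), len(sites), 3), np.nan)
        like[i, j] = df[["L_AA", "L_Aa", "L_aa"]].to_numpy(float)
        if "missing" in df.columns:
            miss = np.zeros((len(individuals), len(sites)), dtype=bool)
            miss[i, j] = df["missing"].to_numpy(bool)
        else:
            miss = np.isnan(like).any(axis=2)
        like = np.nan_to_num(like, nan=1.0 / 3.0)
        return cls(
            individuals=individuals, sites=sites, likelihoods=like, missing=miss
        )


@dataclass(frozen=True)
class SiteFilterConfig:
    """Site filters: SNP p-value below ``snp_p_max``, minor allele frequency
    at least ``maf_min``, data present in at least ``presence_min`` of
    individuals."""

    snp_p_max: float = 1e-6
    maf_min: float = 0.05
    presence_min: float = 0.50

    def __post_init__(self) -> None:
        for name in ("snp_p_max", "maf_min", "presence_min"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")


def _hwe(f: np.ndarray) -> np.ndarray:
    """Genotype frequencies [(1-f)^2, 2f(1-f), f^2]; f may be an array."""
    f = np.asarray(f, dtype=float)
    return np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=-1)


def _ml_freq_all(like: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """EM maximum-likelihood allele frequency per site (vectorized).

    like: N x S x 3, missing: N x S.  Sites where every individual is missing
    get NaN.
    """
    n, s, _ = like.shape
    obs = ~missing  # N x S
    n_obs = obs.sum(axis=0)
    f = np.full(s, 0.2)
    active = n_obs > 0
    g = np.array([0.0, 1.0, 2.0])
    for _ in range(_EM_MAX_ITER):
        w = like * _hwe(f)[None, :, :]  # N x S x 3
        denom = w.sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            dosage = (w @ g) / denom
        dosage = np.where(obs, dosage, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_new = dosage.sum(axis=0) / (2.0 * n_obs)
        f_new = np.where(active, f_new, np.nan)
        delta = np.nanmax(np.abs(np.where(active, f_new - f, 0.0)), initial=0.0)
        f = np.where(active, f_new, f)
        if delta < _EM_TOL:
            break
    return np.where(active, f, np.nan)


def ml_allele_frequency(l_site: np.ndarray, missing: np.ndarray | None = None) -> float:
    """Maximum-likelihood alternate-allele frequency at one site under a
    Hardy-Weinberg prior, from per-individual 3-genotype likelihoods."""
    l_site = np.asarray(l_site, dtype=float)
    if l_site.ndim != 2 or l_site.shape[1] != 3:
        raise ValueError("expected an individuals x 3 likelihood array")
    if missing is None:
        missing = np.zeros(l_site.shape[0], dtype=bool)
    missing = np.asarray(missing, dtype=bool)
    if missing.all():
        raise ValueError("all individuals missing at this site")
    f = _ml_freq_all(l_site[:, None, :], missing[:, None])
    return float(f[0])


def _loglik(like: np.ndarray, missing: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Per-site log-likelihood sum_ind log sum_g L(g) HWE(g|f)."""
    mix = (like * _hwe(f)[None, :, :]).sum(axis=2)
    mix = np.where(missing, 1.0, mix)
    with np.errstate(divide="ignore"):
        ll = np.log(mix)
    return ll.sum(axis=0)


def _snp_lrt_all(like: np.ndarray, missing: np.ndarray):
    f_hat = _ml_freq_all(like, missing)
    f_safe = np.nan_to_num(f_hat, nan=0.0)
    s = like.shape[1]
    ll_hat = _loglik(like, missing, f_safe)
    ll0 = _loglik(like, missing, np.zeros(s))
    ll1 = _loglik(like, missing, np.ones(s))
    stat = 2.0 * (ll_hat - np.maximum(ll0, ll1))
    stat = np.clip(stat, 0.0, None)
    p = chi2.sf(stat, df=1)
    return f_hat, stat, p


def snp_lrt(l_site: np.ndarray, missing: np.ndarray | None = None) -> float:
    """Likelihood-ratio SNP p-value at one site: 2*[l(f_hat) - max(l(0), l(1))]
    against a chi-square with 1 df (no boundary point-mass correction; this
    is conservative)."""
    l_site = np.asarray(l_site, dtype=float)
    if missing is None:
        missing = np.zeros(l_site.shape[0], dtype=bool)
    _, _, p = _snp_lrt_all(l_site[:, None, :], np.asarray(missing, bool)[:, None])
    return float(p[0])


def filter_sites(
    gl: GenotypeLikelihoods, cfg: SiteFilterConfig | None = None
) -> GenotypeLikelihoods:
    """Apply the presence, SNP-LRT and MAF gates (all three must pass).

    The gates are independent, so the result does not depend on their order;
    they are evaluated presence -> LRT -> MAF.
    """
    cfg = cfg or SiteFilterConfig()
    presence = (~gl.missing).mean(axis=0)
    present_ok = presence >= cfg.presence_min
    f_hat, _, p = _snp_lrt_all(gl.likelihoods, gl.missing)
    lrt_ok = np.nan_to_num(p, nan=1.0) < cfg.snp_p_max
    maf = np.minimum(np.nan_to_num(f_hat, nan=0.0), 1.0 - np.nan_to_num(f_hat, nan=0.0))
    maf_ok = maf >= cfg.maf_min
    keep = present_ok & lrt_ok & maf_ok
    logger.info(
        "site filters: %d/%d pass presence, %d pass +LRT, %d pass +MAF",
        int(present_ok.sum()),
        gl.n_sites,
        int((present_ok & lrt_ok).sum()),
        int(keep.sum()),
    )
    if not keep.any():
        logger.warning("no sites survived the genotype-likelihood filters")
    return gl.subset_sites(keep)


@dataclass
class HostStructure:
    """Host PCA: per-site ML allele frequencies, the individual x individual
    posterior-dosage covariance, principal components, and a forced
    two-cluster assignment (labels 1/2) from PC1."""

    individuals: list[str]
    sites: np.ndarray
    allele_freqs: np.ndarray
    covariance: np.ndarray
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    cluster_labels: np.ndarray

    def coordinates_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coordinates,
            index=self.individuals,
            columns=[f"PC{i+1}" for i in range(self.coordinates.shape[1])],
        )
        df.insert(0, "cluster", self.cluster_labels)
        return df


def _kmeans_1d_two(x: np.ndarray) -> np.ndarray:
    """Two-means on a 1-D vector with deterministic initialization at the two
    extremes.  Returns labels in {1, 2}; label 1 is the cluster with the
    smaller mean."""
    centers = np.array([x.min(), x.max()])
    labels = np.zeros(len(x), dtype=int)
    for _ in range(100):
        new_labels = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        if (new_labels == labels).all() and _ > 0:
            break
        labels = new_labels
        for k in (0, 1):
            if (labels == k).any():
                centers[k] = x[labels == k].mean()
    means = [x[labels == k].mean() if (labels == k).any() else np.inf for k in (0, 1)]
    low = int(np.argmin(means))
    return np.where(labels == low, 1, 2)


def genotype_covariance_pca(gl: GenotypeLikelihoods) -> HostStructure:
    """One-pass posterior-dosage covariance PCA of genotype likelihoods.

    Per (individual, site) the posterior mean dosage E[g] is computed under a
    Hardy-Weinberg prior at the site's ML allele frequency, standardized by
    sqrt(2 f (1-f)); the covariance across sites uses pairwise-complete
    entries for missing data.  Individuals are split into two clusters on PC1.
    """
    if gl.n_sites < 2:
        raise ValueError("need at least 2 filtered sites for PCA")
    if gl.n_individuals < 3:
        raise ValueError("need at least 3 individuals for PCA")
    f = _ml_freq_all(gl.likelihoods, gl.missing)
    poly = np.nan_to_num(f * (1 - f), nan=0.0) > 0
    if not poly.any():
        raise ValueError("all sites monomorphic; covariance degenerate")
    if not poly.all():
        logger.info("dropping %d monomorphic sites before PCA", int((~poly).sum()))
        gl = gl.subset_sites(poly)
        f = f[poly]
        if gl.n_sites < 2:
            raise ValueError("fewer than 2 polymorphic sites; covariance degenerate")
    w = gl.likelihoods * _hwe(f)[None, :, :]
    dosage = (w @ np.array([0.0, 1.0, 2.0])) / w.sum(axis=2)
    x = (dosage - 2 * f[None, :]) / np.sqrt(2 * f * (1 - f))[None, :]
    x = np.where(gl.missing, np.nan, x)
    z = np.nan_to_num(x, nan=0.0)
    m = (~gl.missing).astype(float)
    pair_counts = m @ m.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = (z @ z.T) / pair_counts
    cov = np.nan_to_num(cov, nan=0.0)
    cov = (cov + cov.T) / 2.0
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = vecs * np.sqrt(np.clip(vals, 0.0, None))
    labels = _kmeans_1d_two(coords[:, 0])
    return HostStructure(
        individuals=list(gl.individuals),
        sites=gl.sites,
        allele_freqs=f,
        covariance=cov,
        coordinates=coords,
        eigenvalues=vals,
        cluster_labels=labels,
    )


def host_distance(structure: HostStructure, k_axes: int | None = None) -> DistanceMatrix:
    """Euclidean distances between individuals in PC space.

    By default all axes with a positive eigenvalue are used, in which case
    the distances equal those computed directly from the standardized dosage
    matrix (up to the covariance normalization).
    """
    if k_axes is None:
        keep = structure.eigenvalues > 1e-12 * max(
            structure.eigenvalues.max(initial=0.0), 1e-300
        )
    else:
        if k_axes < 1 or k_axes > structure.coordinates.shape[1]:
            raise ValueError("k_axes out of range")
        keep = np.zeros(structure.coordinates.shape[1], dtype=bool)
        keep[:k_axes] = True
    coords = structure.coordinates[:, keep]
    dist = squareform(pdist(coords, metric="euclidean"))
    return DistanceMatrix(labels=list(structure.individuals), values=dist)
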