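"""Co-diversification machinery: PCoA with Cailliez correction, the global
ParaFit permutation test, Ward clustering of SNV variability profiles, and
partition-congruence summaries.

The ParaFit test asks whether the distance structure of a host population and
the distance structure of its symbiont populations are congruent, given a 0/1
host-symbiont association matrix.  Both distance matrices are embedded by
principal coordinates analysis (with the Cailliez additive correction applied
when negative eigenvalues appear), the trace statistic
``sum((C' A B)**2)`` is computed from the two coordinate matrices and the
association matrix, and significance is assessed by permuting host identities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "DistanceMatrix",
    "PcoaResult",
    "ParafitResult",
    "WardResult",
    "pcoa",
    "cailliez_constant",
    "parafit_global",
    "ward_cluster",
    "congruence",
]

_SYMMETRY_TOL = 1e-10


@dataclass
class DistanceMatrix:
    """A labelled square symmetric distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"distance matrix shape {self.values.shape} does not match "
                f"{n} labels"
            )
        if np.isnan(self.values).any():
            raise ValueError("distance matrix contains NaN entries")
        if (self.values < 0).any():
            raise ValueError("distance matrix contains negative entries")
        if np.abs(self.values - self.values.T).max(initial=0.0) > _SYMMETRY_TOL:
            raise ValueError("distance matrix is not symmetric")
        # symmetrize exactly and zero the diagonal
        self.values = (self.values + self.values.T) / 2.0
        if np.abs(np.diag(self.values)).max(initial=0.0) > _SYMMETRY_TOL:
            raise ValueError("distance matrix diagonal is not zero")
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", index_label="label"
        )

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=[str(c) for c in df.columns], values=df.to_numpy(float))


@dataclass
class PcoaResult:
    """Principal coordinates of a distance matrix.

    ``coordinates`` has one row per object and one column per axis; axes whose
    eigenvalue is at or below the positivity tolerance carry zero coordinates.
    ``correction`` is the Cailliez constant added to the off-diagonal
    distances (0.0 when no correction was needed or requested).
    """

    labels: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    correction: float
    n_negative_pre: int

    @property
    def positive_coordinates(self) -> np.ndarray:
        tol = 1e-8 * max(self.eigenvalues.max(initial=0.0), 0.0)
        keep = self.eigenvalues > tol
        return self.coordinates[:, keep]


def _gower_center(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def cailliez_constant(d: np.ndarray) -> float:
    """Smallest additive constant c such that d + c (off-diagonal) has a
    Euclidean embedding: the largest real eigenvalue of the 2n x 2n block
    matrix [[0, 2*D1], [-I, -4*D2]] with D1 the Gower-centered -d^2/2 and D2
    the Gower-centered -d/2."""
    n = d.shape[0]
    d1 = _gower_center(-0.5 * d**2)
    d2 = _gower_center(-0.5 * d)
    block = np.block(
        [[np.zeros((n, n)), 2.0 * d1], [-np.eye(n), -4.0 * d2]]
    )
    eig = np.linalg.eigvals(block)
    real = eig.real[np.abs(eig.imag) <= 1e-8 * (1.0 + np.abs(eig.real))]
    c = float(real.max())
    return max(c, 0.0)


def _pcoa_eig(d: np.ndarray):
    g = _gower_center(-0.5 * d**2)
    vals, vecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def pcoa(d: DistanceMatrix, correction: str = "cailliez_if_needed") -> PcoaResult:
    """Principal coordinates analysis (metric MDS).

    Parameters
    ----------
    d : DistanceMatrix
    correction : {"none", "cailliez_if_needed"}
        With ``cailliez_if_needed`` the Cailliez additive constant is applied
        when the smallest eigenvalue falls below ``-1e-8 * max_eigenvalue``.
    """
    if correction not in ("none", "cailliez_if_needed"):
        raise ValueError(f"unknown correction {correction!r}")
    if d.n < 2:
        raise ValueError("PCoA needs at least 2 objects")
    mat = d.values
    vals, vecs = _pcoa_eig(mat)
    c = 0.0
    n_negative_pre = int((vals < -1e-8 * max(vals.max(), 0.0)).sum())
    if correction == "cailliez_if_needed" and n_negative_pre > 0:
        c = cailliez_constant(mat)
        mat = mat + c
        np.fill_diagonal(mat, 0.0)
        vals, vecs = _pcoa_eig(mat)
    tol = 1e-8 * max(vals.max(), 0.0)
    scale = np.where(vals > tol, np.sqrt(np.clip(vals, 0.0, None)), 0.0)
    coords = vecs * scale
    return PcoaResult(
        labels=list(d.labels),
        coordinates=coords,
        eigenvalues=vals,
        correction=c,
        n_negative_pre=n_negative_pre,
    )


@dataclass
class ParafitResult:
    """Result of the global ParaFit permutation test.

    ``p_value`` uses the add-one permutation estimator
    ``(1 + #{perm >= observed}) / (1 + n_permutations)`` so the smallest
    attainable p at 1000 permutations is 1/1001.
    """

    statistic: float
    p_value: float
    n_permutations: int
    permutation_stats: np.ndarray = field(repr=False)
    seed: int | None
    host_correction: float
    sym_correction: float
    n_host_axes: int
    n_sym_axes: int

    def to_json(self, path) -> None:
        payload = {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "host_cailliez_constant": self.host_correction,
            "sym_cailliez_constant": self.sym_correction,
            "n_host_axes": self.n_host_axes,
            "n_sym_axes": self.n_sym_axes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def parafit_global(
    host_d: DistanceMatrix,
    sym_d: DistanceMatrix,
    assoc: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
) -> ParafitResult:
    """Global ParaFit test of host-symbiont congruence.

    ``assoc`` is the 0/1 association matrix with one row per symbiont
    (ordered as ``sym_d.labels``) and one column per host (ordered as
    ``host_d.labels``); every symbiont must be linked to at least one host.
    The null distribution permutes host identities (columns of ``assoc``),
    which for a one-to-one association is the classic ParaFit row shuffle.
    """
    assoc = np.asarray(assoc)
    if assoc.shape != (sym_d.n, host_d.n):
        raise ValueError(
            f"association matrix shape {assoc.shape} does not match "
            f"{sym_d.n} symbionts x {host_d.n} hosts"
        )
    if not np.isin(assoc, (0, 1)).all():
        raise ValueError("association matrix must be 0/1")
    if (assoc.sum(axis=1) < 1).any():
        raise ValueError("every symbiont must be linked to at least one host")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    host_pc = pcoa(host_d, "cailliez_if_needed")
    sym_pc = pcoa(sym_d, "cailliez_if_needed")
    b = host_pc.positive_coordinates  # hosts x axes
    c = sym_pc.positive_coordinates  # symbionts x axes

    # E[k, j] = sum_i C[i, k] * A[i, j]  (symbiont axes x hosts)
    e = c.T @ assoc
    observed = float(np.sum((e @ b) ** 2))

    rng = np.random.default_rng(seed)
    n_hosts = host_d.n
    perms = np.array([rng.permutation(n_hosts) for _ in range(n_perm)])
    if e.size == 0 or b.size == 0:
        perm_stats = np.zeros(n_perm)
    else:
        ep = e[:, perms]  # axes_c x n_perm x hosts
        dmat = np.einsum("kpn,nj->pkj", ep, b)
        perm_stats = (dmat**2).sum(axis=(1, 2))

    tie_tol = 1e-12 * max(1.0, observed)
    n_ge = int((perm_stats >= observed - tie_tol).sum())
    p = (1.0 + n_ge) / (1.0 + n_perm)
    return ParafitResult(
        statistic=observed,
        p_value=p,
        n_permutations=n_perm,
        permutation_stats=perm_stats,
        seed=seed,
        host_correction=host_pc.correction,
        sym_correction=sym_pc.correction,
        n_host_axes=b.shape[1],
        n_sym_axes=c.shape[1],
    )


@dataclass
class WardResult:
    labels: list[str]
    linkage: np.ndarray
    newick: str
    cluster_labels: np.ndarray  # k=2 cut, values in {1, 2}


def _linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Newick with branch lengths = parent merge height - child merge height."""
    tree = hierarchy.to_tree(z)

    def build(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    left = build(tree.left, tree.dist)
    right = build(tree.right, tree.dist)
    return f"({left},{right});"


def ward_cluster(profile_matrix: np.ndarray, labels: list[str]) -> WardResult:
    """Ward-linkage hierarchical clustering of samples on Euclidean distances.

    ``profile_matrix`` is samples x features (e.g. SNV departure values).
    Returns the linkage matrix, a Newick dendrogram whose branch lengths are
    merge-height differences, and a two-cluster cut of the top merge.
    """
    x = np.asarray(profile_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")
    if x.shape[0] != len(labels):
        raise ValueError("label count does not match row count")
    z = hierarchy.linkage(x, method="ward")
    newick = _linkage_to_newick(z, list(labels))
    cut = hierarchy.fcluster(z, t=2, criterion="maxclust")
    return WardResult(
        labels=list(labels), linkage=z, newick=newick, cluster_labels=cut
    )


def congruence(host_labels, sym_labels) -> dict:
    """Chance-corrected agreement between host and symbiont partitions.

    Returns the adjusted Rand index and the contingency table of the two
    labelings (a 2x2 table for two-cluster partitions).
    """
    host_labels = np.asarray(host_labels)
    sym_labels = np.asarray(sym_labels)
    if host_labels.shape != sym_labels.shape:
        raise ValueError("partitions must label the same objects")
    ari = float(adjusted_rand_score(host_labels, sym_labels))
    table = pd.crosstab(
        pd.Series(host_labels, name="host"), pd.Series(sym_labels, name="symbiont")
    )
    return {"ari": ari, "contingency": table}
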