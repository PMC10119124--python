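"""PCoA/Cailliez contracts, ParaFit permutation inference, Ward clustering,
and partition congruence — including independent cross-checks against the R
ape implementations."""

import itertools
import subprocess

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from codivkit.codiv_test import (
    DistanceMatrix,
    cailliez_constant,
    congruence,
    parafit_global,
    pcoa,
    ward_cluster,
)


def _dm(values, prefix="x"):
    values = np.asarray(values, float)
    return DistanceMatrix([f"{prefix}{i}" for i in range(len(values))], values)


def _points_dm(points, prefix="x"):
    return _dm(squareform(pdist(np.asarray(points, float))), prefix)


def test_distance_matrix_validation():
    with pytest.raises(ValueError):
        _dm([[0, 1], [2, 0]])  # asymmetric
    with pytest.raises(ValueError):
        _dm([[1, 1], [1, 0]])  # nonzero diagonal
    with pytest.raises(ValueError):
        _dm([[0, -1], [-1, 0]])  # negative


def test_pcoa_collinear_points_have_one_positive_axis():
    d = _points_dm([[0.0], [1.0], [3.0]])
    res = pcoa(d)
    tol = 1e-8 * res.eigenvalues.max()
    assert (res.eigenvalues > tol).sum() == 1
    recon = squareform(pdist(res.coordinates))
    assert np.allclose(recon, d.values, atol=1e-10)


def test_pcoa_euclidean_input_needs_no_correction(rng):
    d = _points_dm(rng.normal(size=(7, 3)))
    res = pcoa(d)
    assert res.correction == 0.0
    assert res.n_negative_pre == 0
    recon = squareform(pdist(res.positive_coordinates))
    assert np.allclose(recon, d.values, atol=1e-8)


def test_cailliez_removes_negative_eigenvalues_of_4_point_metric():
    # all pairs at 1 except one pair at 2: metric but not Euclidean
    values = np.ones((4, 4)) - np.eye(4)
    values[0, 1] = values[1, 0] = 2.0
    d = _dm(values)
    uncorrected = pcoa(d, correction="none")
    assert uncorrected.eigenvalues.min() < -1e-8 * uncorrected.eigenvalues.max()
    res = pcoa(d, correction="cailliez_if_needed")
    assert res.correction > 0.0
    assert res.n_negative_pre >= 1
    assert res.eigenvalues.min() >= -1e-8 * res.eigenvalues.max()
    # off-diagonal distances all increased by the same constant
    corrected = values + res.correction
    np.fill_diagonal(corrected, 0.0)
    again = pcoa(_dm(corrected), correction="none")
    assert again.eigenvalues.min() >= -1e-8 * again.eigenvalues.max()


def test_cailliez_constant_and_eigenvalues_match_ape(rng):
    n = 6
    m = rng.uniform(0.5, 2.0, (n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    res = pcoa(_dm(m))
    assert res.n_negative_pre > 0 and res.correction > 0
    script = (
        "suppressMessages(library(ape));"
        "D <- as.matrix(read.csv('m.csv', header=FALSE));"
        "r <- pcoa(as.dist(D), correction='cailliez');"
        "cat(r$values$Corr_eig, sep='\\n')"
    )
    import tempfile, os

    with tempfile.TemporaryDirectory() as td:
        np.savetxt(os.path.join(td, "m.csv"), m, delimiter=",")
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, cwd=td
        )
    assert out.returncode == 0, out.stderr
    ape_eigs = np.sort(np.array([float(x) for x in out.stdout.split()]))[::-1]
    mine = np.sort(res.eigenvalues)[::-1][: len(ape_eigs)]
    assert np.allclose(mine, ape_eigs, atol=1e-6)


def test_parafit_statistic_matches_ape(rng):
    hd = _points_dm(rng.normal(size=(5, 3)), "h")
    sd = _points_dm(rng.normal(size=(5, 3)), "s")
    res = parafit_global(hd, sd, np.eye(5, dtype=int), n_perm=9, seed=0)
    script = (
        "suppressMessages(library(ape));"
        "HD <- as.matrix(read.csv('hd.csv', header=FALSE));"
        "SD <- as.matrix(read.csv('sd.csv', header=FALSE));"
        "r <- parafit(HD, SD, diag(5), nperm=9, silent=TRUE);"
        "cat(r$ParaFitGlobal, '\\n')"
    )
    import tempfile, os

    with tempfile.TemporaryDirectory() as td:
        np.savetxt(os.path.join(td, "hd.csv"), hd.values, delimiter=",")
        np.savetxt(os.path.join(td, "sd.csv"), sd.values, delimiter=",")
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, cwd=td
        )
    assert out.returncode == 0, out.stderr
    assert res.statistic == pytest.approx(float(out.stdout.split()[0]), rel=1e-5)


def test_parafit_degenerate_symbiont_distances_give_p_one():
    hd = _points_dm([[0.0], [1.0], [2.0], [4.0]], "h")
    sd = _dm(np.zeros((4, 4)), "s")
    res = parafit_global(hd, sd, np.eye(4, dtype=int), n_perm=99, seed=1)
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_parafit_exhaustive_enumeration_on_paired_structure():
    """Two tight host pairs mirrored by two tight symbiont pairs: the
    identity association maximizes the statistic over all 4! host-label
    permutations, and the sampled permutation p agrees with the exhaustive
    one within binomial error."""
    host_pts = np.array([[0.0], [0.1], [10.0], [10.1]])
    sym_pts = np.array([[0.0], [0.2], [8.0], [8.3]])
    hd = _points_dm(host_pts, "h")
    sd = _points_dm(sym_pts, "s")
    assoc = np.eye(4, dtype=int)

    from codivkit.codiv_test import pcoa as _pcoa

    b = _pcoa(hd).positive_coordinates
    c = _pcoa(sd).positive_coordinates
    e = c.T @ assoc
    stats = []
    for perm in itertools.permutations(range(4)):
        stats.append(float(np.sum((e[:, perm] @ b) ** 2)))
    observed = stats[0]  # identity permutation
    assert observed == pytest.approx(max(stats), rel=1e-12)
    exhaustive_p = np.mean([s >= observed - 1e-12 for s in stats])

    res = parafit_global(hd, sd, assoc, n_perm=999, seed=5)
    assert res.statistic == pytest.approx(observed, rel=1e-12)
    se = np.sqrt(exhaustive_p * (1 - exhaustive_p) / 999)
    assert abs(res.p_value - exhaustive_p) < 4 * se + 2 / 999


def test_parafit_deterministic_under_fixed_seed(rng):
    hd = _points_dm(rng.normal(size=(6, 2)), "h")
    sd = _points_dm(rng.normal(size=(6, 2)), "s")
    a = parafit_global(hd, sd, np.eye(6, dtype=int), n_perm=199, seed=42)
    b = parafit_global(hd, sd, np.eye(6, dtype=int), n_perm=199, seed=42)
    assert a.p_value == b.p_value
    assert np.array_equal(a.permutation_stats, b.permutation_stats)
    assert 0.0 < a.p_value <= 1.0
    assert a.p_value >= 1.0 / 200.0


def test_parafit_input_validation(rng):
    hd = _points_dm(rng.normal(size=(4, 2)), "h")
    sd = _points_dm(rng.normal(size=(3, 2)), "s")
    with pytest.raises(ValueError):
        parafit_global(hd, sd, np.eye(4, dtype=int), n_perm=9)
    bad = np.zeros((3, 4), dtype=int)
    with pytest.raises(ValueError):
        parafit_global(hd, sd, bad, n_perm=9)  # unlinked symbiont
    with pytest.raises(ValueError):
        parafit_global(hd, sd, np.ones((3, 4), dtype=int), n_perm=0)


def test_ward_duplicates_merge_first_at_height_zero():
    x = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
    res = ward_cluster(x, ["a", "b", "c"])
    assert res.linkage[0, 2] == pytest.approx(0.0)
    assert sorted(res.linkage[0, :2]) == [0, 1]


def test_ward_two_block_matrix_cut_recovers_blocks():
    x = np.zeros((6, 8))
    x[:3, :4] = 0.5
    x[3:, 4:] = 0.5
    res = ward_cluster(x, [f"s{i}" for i in range(6)])
    labels = res.cluster_labels
    assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
    assert labels[0] != labels[3]


def naive_ward_heights(x):
    """O(n^3) Lance-Williams Ward linkage; returns sorted merge heights."""
    d = squareform(pdist(x)).astype(float)
    n = len(x)
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    dist = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    heights = []
    nxt = n
    while len(active) > 1:
        (i, j), h = min(
            ((k, v) for k, v in dist.items() if k[0] in active and k[1] in active),
            key=lambda kv: (kv[1], kv[0]),
        )
        heights.append(h)
        ni, nj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            nk = sizes[k]
            new = np.sqrt(
                ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * h**2)
                / (ni + nj + nk)
            )
            dist[tuple(sorted((nxt, k)))] = new
        sizes[nxt] = ni + nj
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    return np.array(heights)


def test_ward_merge_heights_match_naive_lance_williams(rng):
    x = rng.normal(size=(8, 5))
    res = ward_cluster(x, [f"s{i}" for i in range(8)])
    assert np.allclose(res.linkage[:, 2], naive_ward_heights(x), atol=1e-8)


def test_ward_newick_is_parseable_with_correct_leaves_and_depths(rng):
    from io import StringIO

    from Bio import Phylo

    x = rng.normal(size=(6, 4))
    labels = [f"smp{i}" for i in range(6)]
    res = ward_cluster(x, labels)
    tree = Phylo.read(StringIO(res.newick), "newick")
    leaves = sorted(t.name for t in tree.get_terminals())
    assert leaves == sorted(labels)
    # every leaf sits at depth equal to the root merge height
    root_height = res.linkage[-1, 2]
    for leaf in tree.get_terminals():
        assert tree.distance(leaf) == pytest.approx(root_height, abs=1e-6)


def test_congruence_examples_and_null_calibration(rng):
    a = [1, 1, 2, 2]
    assert congruence(a, [2, 2, 1, 1])["ari"] == 1.0
    assert congruence(a, [1, 1, 1, 1])["ari"] == 0.0
    table = congruence(a, [1, 2, 1, 2])["contingency"]
    assert table.to_numpy().sum() == 4
    aris = []
    for _ in range(500):
        aris.append(
            congruence(rng.integers(1, 3, 20), rng.integers(1, 3, 20))["ari"]
        )
    assert abs(float(np.mean(aris))) < 0.05
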