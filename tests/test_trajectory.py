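"""Pseudotime binning, DTW alignment, transfer, gene activity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import sparse, stats

from skelconv import pseudobulk, trajectory


def _bins_from_matrix(M, centers):
    """Build a TrajectoryBins directly (bypassing cell-level binning)."""
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, keepdims=True)
    Z = np.where(sd > 0, (M - mu) / np.where(sd > 0, sd, 1), 0.0)
    ids = [f"f{i}" for i in range(M.shape[0])]
    cols = [f"bin{i}" for i in range(M.shape[1])]
    return trajectory.TrajectoryBins(
        edges=np.linspace(0, 1, M.shape[1] + 1),
        centers=np.asarray(centers),
        counts=np.ones(M.shape[1], dtype=int),
        means=pd.DataFrame(M, index=ids, columns=cols),
        zscores=pd.DataFrame(Z, index=ids, columns=cols),
    )


def test_bin_pseudotime_hand_oracle():
    X = sparse.csr_matrix(np.array([[1.0, 2.0, 3.0, 10.0], [0.0, 1.0, 0.0, 4.0]]))
    t = np.array([0.0, 0.25, 0.5, 1.0])
    tb = trajectory.bin_pseudotime(X, ["a", "b"], t, n_bins=2)
    assert list(tb.counts) == [3, 1]
    np.testing.assert_allclose(tb.means.loc["a"], [2.0, 10.0])
    np.testing.assert_allclose(tb.means.loc["b"], [1.0 / 3.0, 4.0])


def test_bin_pseudotime_constant_feature_zero_z():
    X = sparse.csr_matrix(np.ones((1, 20)))
    t = np.linspace(0, 1, 20)
    tb = trajectory.bin_pseudotime(X, ["c"], t, n_bins=4)
    assert (tb.zscores.loc["c"] == 0).all()


def test_bin_pseudotime_rejects_degenerate_inputs():
    X = sparse.csr_matrix(np.ones((1, 5)))
    with pytest.raises(ValueError):
        trajectory.bin_pseudotime(X, ["a"], np.zeros(5), n_bins=3)
    with pytest.raises(ValueError):
        trajectory.bin_pseudotime(X, ["a"], np.linspace(0, 1, 5), n_bins=1)


def test_planted_module_bin_means_nondecreasing(small_cohort):
    co = small_cohort
    norm = pseudobulk.normalize_log(co.rna.X)
    module = sorted(set().union(*co.truth.module_genes))
    rows = [co.rna.feature_ids.index(g) for g in module]
    per_cell = np.asarray(norm[rows].mean(axis=0)).ravel()
    for lin in ("NC", "SOM", "LPM"):
        m = (co.rna.cells["lineage"] == lin).to_numpy()
        tb = trajectory.bin_pseudotime(
            norm[:, np.flatnonzero(m)], co.rna.feature_ids,
            co.rna.cells.loc[m, "pseudotime"].to_numpy(), 8,
        )
        prof = tb.means.loc[module].mean(axis=0).to_numpy()
        # sampling band: per-cell module-mean spread over the bin populations
        se = per_cell[m].std() / np.sqrt(tb.counts.min())
        assert np.all(np.diff(prof) > -3 * se)
        assert prof[-1] > prof[0] + 1.0  # and the planted rise is large


def dtw_exhaustive(D):
    """Enumerate every monotone corner-to-corner path (test oracle)."""
    n, m = D.shape
    best = [np.inf]

    def rec(i, j, cost):
        cost += D[i, j]
        if cost >= best[0]:
            return
        if (i, j) == (n - 1, m - 1):
            best[0] = cost
            return
        if i + 1 < n and j + 1 < m:
            rec(i + 1, j + 1, cost)
        if i + 1 < n:
            rec(i + 1, j, cost)
        if j + 1 < m:
            rec(i, j + 1, cost)

    rec(0, 0, 0.0)
    return best[0]


@pytest.mark.parametrize("shape", [(3, 3), (5, 4), (8, 8), (2, 7)])
def test_dtw_cost_equals_exhaustive_oracle(shape, rng):
    for _ in range(5):
        D = rng.uniform(0, 1, size=shape)
        assert trajectory.dtw_full_cost(D) == pytest.approx(dtw_exhaustive(D))


def _random_profiles(rng, n_feat=20, n_bins=25):
    t = np.linspace(0, 1, n_bins)
    phase = rng.uniform(0, 2 * np.pi, n_feat)
    freq = rng.uniform(0.5, 2.0, n_feat)
    return np.sin(np.outer(freq, t) * np.pi + phase[:, None]) + 0.05 * rng.normal(
        size=(n_feat, n_bins)
    )


def test_identity_alignment_is_diagonal(rng):
    M = _random_profiles(rng)
    bins = _bins_from_matrix(M, np.linspace(0, 1, M.shape[1]))
    res = trajectory.align_trajectories(bins, bins, list(bins.means.index), n_points=30)
    assert res.path == [(i, i) for i in range(30)]
    np.testing.assert_allclose(res.matched_dissimilarity, 0, atol=1e-12)
    assert len(res.unmatched_a[0]) == len(res.unmatched_a[1]) == 0
    assert len(res.unmatched_b[0]) == len(res.unmatched_b[1]) == 0


def test_known_monotone_warp_recovered(rng):
    M = _random_profiles(rng, n_feat=30, n_bins=40)
    centers = np.linspace(0, 1, 40)
    bins_a = _bins_from_matrix(M, centers)
    # warp: B's clock runs as g(t) = t**1.6 of A's clock
    warped = np.vstack([np.interp(centers**1.6, centers, row) for row in M])
    bins_b = _bins_from_matrix(warped, centers)
    res = trajectory.align_trajectories(bins_a, bins_b, list(bins_a.means.index), n_points=40)
    # true correspondence: B index j matches A position 40 * g(t_j)
    for i, j in res.path:
        true_i = (centers[j] ** 1.6) * 39
        assert abs(i - true_i) <= 2.0


def test_terminal_extension_reported_unmatched(rng):
    M = _random_profiles(rng, n_feat=30, n_bins=30)
    centers = np.linspace(0, 1, 30)
    bins_a = _bins_from_matrix(M, centers)
    ext = _random_profiles(np.random.default_rng(99), n_feat=30, n_bins=10)
    bins_b = _bins_from_matrix(np.hstack([M, ext + 3]), np.linspace(0, 1, 40))
    res = trajectory.align_trajectories(bins_a, bins_b, list(bins_a.means.index),
                                        n_points=40)
    trailing_b = res.unmatched_b[1]
    assert len(trailing_b) >= 6  # the divergent terminal stretch is cut
    assert len(res.unmatched_a[0]) + len(res.unmatched_a[1]) <= 4


def test_alignment_symmetric_up_to_transposition(rng):
    A = _random_profiles(rng, n_feat=25, n_bins=20)
    B = _random_profiles(rng, n_feat=25, n_bins=20)
    centers = np.linspace(0, 1, 20)
    ba, bb = _bins_from_matrix(A, centers), _bins_from_matrix(B, centers)
    r1 = trajectory.align_trajectories(ba, bb, list(ba.means.index), n_points=15)
    r2 = trajectory.align_trajectories(bb, ba, list(ba.means.index), n_points=15)
    assert [(j, i) for i, j in r1.path] == r2.path


def test_constant_profile_errors_name_feature():
    M = np.vstack([np.linspace(0, 1, 10), np.full(10, 2.0)])
    bins = _bins_from_matrix(M, np.linspace(0, 1, 10))
    with pytest.raises(ValueError, match="f1"):
        trajectory.align_trajectories(bins, bins, ["f0", "f1"], n_points=10)


# ---------------------------------------------------------------------------
# pseudotime transfer


def test_transfer_identity_and_uniform_limits(rng):
    F, n = 30, 15
    R = rng.normal(size=(F, n))
    t = np.linspace(0, 1, n)
    ids = [f"f{i}" for i in range(F)]
    # ATAC profile equal to one RNA cell: k=1 returns that cell's pseudotime
    tr = trajectory.transfer_pseudotime(
        sparse.csr_matrix(R), ids, t, sparse.csr_matrix(R[:, [4]]), ids, k=1
    )
    assert tr[0] == pytest.approx(t[4])
    # k = population with uniform similarity -> mean pseudotime
    uniform = sparse.csr_matrix(np.tile(R[:, [0]], (1, n)))
    tr2 = trajectory.transfer_pseudotime(
        sparse.csr_matrix(np.tile(R[:, [0]], (1, n))), ids, t,
        sparse.csr_matrix(R[:, [0]]), ids, k=n,
    )
    assert tr2[0] == pytest.approx(t.mean())
    with pytest.raises(ValueError):
        trajectory.transfer_pseudotime(sparse.csr_matrix(R), ids, t,
                                       sparse.csr_matrix(R[:, [0]]), ids, k=n + 1)


def test_transfer_recovers_truth_on_paired_cells(small_cohort):
    co = small_cohort
    norm = pseudobulk.normalize_log(co.rna.X)
    act, act_genes = trajectory.gene_activity(co.atac.X, co.peaks, co.genes)
    act_norm = pseudobulk.normalize_log(act)
    tr = trajectory.transfer_pseudotime(
        norm, co.rna.feature_ids, co.rna.cells["pseudotime"].to_numpy(),
        act_norm, act_genes, k=20,
    )
    truth = np.array(
        [co.truth.true_pseudotime[co.truth.paired_cells[a]] for a in co.atac.cells.index]
    )
    assert stats.spearmanr(tr, truth).statistic > 0.9


# ---------------------------------------------------------------------------
# gene activity


def test_gene_activity_matches_interval_oracle(rng):
    genes = pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3"],
            "chrom": ["c1", "c1", "c2"],
            "strand": ["+", "-", "+"],
            "tss": [10_000, 30_000, 5_000],
            "start": [10_000, 26_000, 5_000],
            "end": [14_000, 30_001, 9_000],
        }
    )
    starts = rng.integers(0, 40_000, 60)
    peaks = pd.DataFrame({"peak_id": [f"p{i}" for i in range(60)],
                          "chrom": rng.choice(["c1", "c2"], 60),
                          "start": starts, "end": starts + 300})
    X = rng.poisson(2, size=(60, 5))
    act, ids = trajectory.gene_activity(sparse.csr_matrix(X), peaks, genes, upstream=2000)
    A = np.asarray(act.todense())
    assert ids == ["g1", "g2", "g3"]
    for gi, g in genes.iterrows():
        if g["strand"] == "+":
            lo, hi = g["start"] - 2000, g["end"]
        else:
            lo, hi = g["start"], g["end"] + 2000
        rows = [
            i for i in range(60)
            if peaks.loc[i, "chrom"] == g["chrom"]
            and peaks.loc[i, "start"] < hi and peaks.loc[i, "end"] > lo
        ]
        np.testing.assert_array_equal(A[gi], X[rows].sum(axis=0) if rows else 0)


def test_gene_activity_upstream_zero_drops_promoter_only_peak():
    genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["c1"], "strand": ["+"],
                          "tss": [10_000], "start": [10_000], "end": [12_000]})
    peaks = pd.DataFrame({"peak_id": ["prom", "body"], "chrom": ["c1", "c1"],
                          "start": [9_000, 10_500], "end": [9_500, 11_000]})
    X = sparse.csr_matrix(np.array([[5, 5], [7, 7]]))
    act2000, _ = trajectory.gene_activity(X, peaks, genes, upstream=2000)
    act0, _ = trajectory.gene_activity(X, peaks, genes, upstream=0)
    np.testing.assert_array_equal(np.asarray(act2000.todense())[0], [12, 12])
    np.testing.assert_array_equal(np.asarray(act0.todense())[0], [7, 7])
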