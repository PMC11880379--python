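"""Pseudotime dynamics and cross-lineage trajectory alignment.

Pseudotime is an input (planted truth or user-supplied); this module bins it
into equidistant pseudobulks, interpolates per-feature dynamics, aligns two
trajectories with an open-ended dynamic time warping on Spearman
dissimilarity (1 − rho), transfers pseudotime from RNA to ATAC cells with a
correlation-kNN, and builds gene-activity matrices (promoter + gene body
accessibility) from peak counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pyranges as pr
from scipy import sparse, stats


@dataclass
class TrajectoryBins:
    """Equidistant pseudotime pseudobulks of a feature matrix."""

    edges: np.ndarray           # n_bins+1 edges over [min t, max t]
    centers: np.ndarray         # centers of retained (non-empty) bins
    counts: np.ndarray          # cells per retained bin
    means: pd.DataFrame         # features × retained bins
    zscores: pd.DataFrame       # per-feature z across retained bins


def bin_pseudotime(
    normalized, feature_ids: list[str], pseudotime: np.ndarray, n_bins: int
) -> TrajectoryBins:
    """Bin cells into equal-width pseudotime intervals and average features.

    Empty bins are dropped (with a warning); the z-scored view standardizes
    each feature across the retained bins, with constant features left at 0.
    """
    t = np.asarray(pseudotime, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("pseudotime must be finite")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo, hi = t.min(), t.max()
    if lo == hi:
        raise ValueError("all cells share one pseudotime value")
    edges = np.linspace(lo, hi, n_bins + 1)
    # right-closed bins, lowest edge included in the first bin
    which = np.clip(np.searchsorted(edges, t, side="left") - 1, 0, n_bins - 1)
    X = sparse.csc_matrix(normalized, dtype=float)
    means, centers, counts = [], [], []
    for b in range(n_bins):
        cols = np.flatnonzero(which == b)
        if cols.size == 0:
            continue
        means.append(np.asarray(X[:, cols].mean(axis=1)).ravel())
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        counts.append(cols.size)
    if len(means) < n_bins:
        import warnings

        warnings.warn(f"dropped {n_bins - len(means)} empty pseudotime bins")
    M = np.column_stack(means)
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, keepdims=True)
    Z = np.where(sd > 0, (M - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    cols = [f"bin{idx}" for idx in range(M.shape[1])]
    return TrajectoryBins(
        edges=edges,
        centers=np.array(centers),
        counts=np.array(counts),
        means=pd.DataFrame(M, index=feature_ids, columns=cols),
        zscores=pd.DataFrame(Z, index=feature_ids, columns=cols),
    )


@dataclass
class AlignmentResult:
    """Open-ended DTW alignment of two interpolated trajectories."""

    points_a: np.ndarray        # interpolated profiles, features × n_points
    points_b: np.ndarray
    dissimilarity: np.ndarray   # n_points × n_points matrix of 1 − rho
    path: list[tuple[int, int]]
    matched_dissimilarity: np.ndarray
    unmatched_a: tuple[range, range]   # leading, trailing index ranges of A
    unmatched_b: tuple[range, range]
    mean_cost: float


def _interpolate(bins: TrajectoryBins, features: list[str], n_points: int) -> np.ndarray:
    prof = bins.means.loc[features].to_numpy()
    grid = np.linspace(bins.centers[0], bins.centers[-1], n_points)
    return np.vstack([np.interp(grid, bins.centers, row) for row in prof])


def dtw_full_cost(D: np.ndarray) -> float:
    """Minimum total cost of a full corner-to-corner DTW path.

    Steps {(1,0),(0,1),(1,1)}; the cost of a path is the sum of D over the
    visited cells.
    """
    n, m = D.shape
    acc = np.full((n, m), np.inf)
    acc[0, 0] = D[0, 0]
    for i in range(n):
        for j in range(m):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i > 0:
                best = min(best, acc[i - 1, j])
            if j > 0:
                best = min(best, acc[i, j - 1])
            if i > 0 and j > 0:
                best = min(best, acc[i - 1, j - 1])
            acc[i, j] = D[i, j] + best
    return float(acc[n - 1, m - 1])


def _dp_from(D: np.ndarray, si: int, sj: int):
    """DP of total cost and path length from a fixed start cell."""
    n, m = D.shape
    acc = np.full((n, m), np.inf)
    plen = np.zeros((n, m), dtype=int)
    back = np.full((n, m), -1, dtype=np.int8)  # 0=diag, 1=up, 2=left
    acc[si, sj] = D[si, sj]
    plen[si, sj] = 1
    for i in range(si, n):
        for j in range(sj, m):
            if i == si and j == sj:
                continue
            cands = []
            if i > si and j > sj:
                cands.append((acc[i - 1, j - 1], 0, plen[i - 1, j - 1]))
            if i > si:
                cands.append((acc[i - 1, j], 1, plen[i - 1, j]))
            if j > sj:
                cands.append((acc[i, j - 1], 2, plen[i, j - 1]))
            c, b, pl = min(cands, key=lambda x: x[0])
            if np.isfinite(c):
                acc[i, j] = D[i, j] + c
                plen[i, j] = pl + 1
                back[i, j] = b
    return acc, plen, back


def _traceback(back, si, sj, ei, ej):
    path = [(ei, ej)]
    i, j = ei, ej
    while (i, j) != (si, sj):
        b = back[i, j]
        if b == 0:
            i, j = i - 1, j - 1
        elif b == 1:
            i -= 1
        else:
            j -= 1
        path.append((i, j))
    path.reverse()
    return path


def align_trajectories(
    bins_a: TrajectoryBins,
    bins_b: TrajectoryBins,
    shared_features: list[str],
    n_points: int = 40,
    max_cut: float = 0.5,
) -> AlignmentResult:
    """Align two pseudotime trajectories by open-ended DTW.

    Each shared feature's bin-mean profile is linearly interpolated at
    ``n_points`` equidistant pseudotime positions; the dissimilarity between
    interpolated points i (of A) and j (of B) is 1 − Spearman rho across
    shared features.  DTW (steps diagonal/up/left) is run from every boundary
    start cell (first column of A or first row of B) to every boundary end
    cell; the start/end pair minimizing the mean path cost wins, ties going
    to the pair leaving fewest terminal indices unmatched.  Indices cut off
    before the start or after the end of the chosen path are reported as
    unmatched terminals.  ``max_cut`` caps the unmatched fraction per
    trajectory (a cut may trim terminal mismatched sections, not replace the
    alignment with a corner fragment).
    """
    if len(shared_features) < 2:
        raise ValueError("need at least 2 shared features")
    A = _interpolate(bins_a, shared_features, n_points)
    B = _interpolate(bins_b, shared_features, n_points)
    for name, M in (("A", A), ("B", B)):
        flat = [shared_features[i] for i in np.flatnonzero(M.std(axis=1) == 0)]
        if flat:
            raise ValueError(f"constant profiles in trajectory {name}: {flat}")
    ra = stats.rankdata(A, axis=0)
    rb = stats.rankdata(B, axis=0)
    za = (ra - ra.mean(0)) / ra.std(0)
    zb = (rb - rb.mean(0)) / rb.std(0)
    D = 1.0 - (za.T @ zb) / A.shape[0]
    n, m = D.shape

    min_span_a = int(np.ceil((1 - max_cut) * n))
    min_span_b = int(np.ceil((1 - max_cut) * m))
    starts = [(i, 0) for i in range(n)] + [(0, j) for j in range(1, m)]
    best = None
    for si, sj in starts:
        acc, plen, back = _dp_from(D, si, sj)
        ends = [(n - 1, j) for j in range(sj, m)] + [(i, m - 1) for i in range(si, n - 1)]
        for ei, ej in ends:
            if not np.isfinite(acc[ei, ej]):
                continue
            if ei - si + 1 < min_span_a or ej - sj + 1 < min_span_b:
                continue
            mean_cost = acc[ei, ej] / plen[ei, ej]
            unmatched = si + sj + (n - 1 - ei) + (m - 1 - ej)
            key = (round(mean_cost, 12), unmatched)
            if best is None or key < best[0]:
                best = (key, (si, sj, ei, ej), back)
    (mean_cost_r, _), (si, sj, ei, ej), back = best
    path = _traceback(back, si, sj, ei, ej)
    matched = np.array([D[i, j] for i, j in path])
    return AlignmentResult(
        points_a=A,
        points_b=B,
        dissimilarity=D,
        path=path,
        matched_dissimilarity=matched,
        unmatched_a=(range(0, si), range(ei + 1, n)),
        unmatched_b=(range(0, sj), range(ej + 1, m)),
        mean_cost=float(matched.sum() / len(path)),
    )


def transfer_pseudotime(
    rna_normalized,
    rna_feature_ids: list[str],
    rna_pseudotime: np.ndarray,
    atac_activity,
    atac_feature_ids: list[str],
    k: int = 10,
) -> np.ndarray:
    """Transfer pseudotime to ATAC cells via Spearman-correlation kNN.

    Shared features are z-scored jointly across both modalities; for each
    ATAC cell the ``k`` RNA cells with highest Spearman correlation of the
    shared-feature profile are found and the transferred pseudotime is their
    similarity-weighted mean (non-positive similarities floored to a small
    uniform weight).
    """
    shared = [f for f in rna_feature_ids if f in set(atac_feature_ids)]
    if not shared:
        raise ValueError("no shared features between modalities")
    t = np.asarray(rna_pseudotime, dtype=float)
    Xr = sparse.csr_matrix(rna_normalized, dtype=float)
    Xa = sparse.csr_matrix(atac_activity, dtype=float)
    if k > Xr.shape[1]:
        raise ValueError("k exceeds the RNA population")
    ri = {f: i for i, f in enumerate(rna_feature_ids)}
    ai = {f: i for i, f in enumerate(atac_feature_ids)}
    R = np.asarray(Xr[[ri[f] for f in shared]].todense())  # features × rna cells
    Acts = np.asarray(Xa[[ai[f] for f in shared]].todense())

    both = np.hstack([R, Acts])
    mu = both.mean(axis=1, keepdims=True)
    sd = both.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    R = (R - mu) / sd
    Acts = (Acts - mu) / sd

    def rank_std(M):
        r = stats.rankdata(M, axis=0)
        rc = r - r.mean(0)
        norm = np.sqrt((rc**2).sum(0))
        norm[norm == 0] = 1.0
        return rc / norm

    zr = rank_std(R)
    za = rank_std(Acts)
    rho = za.T @ zr  # atac cells × rna cells
    out = np.empty(rho.shape[0])
    for c in range(rho.shape[0]):
        nb = np.argsort(-rho[c])[:k]
        w = np.maximum(rho[c, nb], 0.0) + 1e-9
        out[c] = np.sum(w * t[nb]) / np.sum(w)
    return out


def gene_activity(
    atac_counts,
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    upstream: int = 2000,
):
    """Gene × cell activity: summed peak counts over gene body plus promoter.

    A peak contributes to a gene when it overlaps the union of the gene body
    and the strand-aware ``upstream`` bp window ahead of the TSS.  Genes with
    no overlapping peak get a zero row.

    Returns ``(matrix, gene_ids)`` with the matrix in CSR genes × cells.
    """
    X = sparse.csr_matrix(atac_counts, dtype=float)
    plus = genes["strand"] == "+"
    ext_start = np.where(plus, genes["start"] - upstream, genes["start"])
    ext_end = np.where(plus, genes["end"], genes["end"] + upstream)
    ext_start = np.maximum(ext_start, 0)
    gene_gr = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": genes["chrom"],
                "Start": ext_start,
                "End": ext_end,
                "gene_idx": np.arange(len(genes)),
            }
        )
    )
    peak_gr = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": peaks["chrom"],
                "Start": peaks["start"],
                "End": peaks["end"],
                "peak_idx": np.arange(len(peaks)),
            }
        )
    )
    joined = gene_gr.join(peak_gr).df
    ind = sparse.csr_matrix(
        (
            np.ones(len(joined)),
            (joined["gene_idx"].to_numpy(), joined["peak_idx"].to_numpy()),
        )
        if len(joined)
        else ((), ([], [])),
        shape=(len(genes), len(peaks)),
    )
    activity = ind @ X
    gene_ids = genes["gene_id"].tolist() if "gene_id" in genes.columns else list(genes.index)
    return activity.tocsr(), gene_ids
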