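"""Peak-to-gene links over cell aggregates, link clustering, cross-lineage
overlap counts and conservation averaging.

Links are called per lineage: accessibility and (pseudo)expression are
averaged over aggregates of cells, candidate peak–gene pairs within a
genomic window of the TSS are scored by Pearson correlation, p-values come
from the t distribution with n_aggregates − 2 df and are BH-adjusted per
lineage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pyranges as pr
from scipy import sparse, stats
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .differential import bh_adjust

logger = logging.getLogger(__name__)


def aggregate_cells(
    n_cells: int,
    n_aggregates: int = 500,
    cells_per: int = 100,
    seed: int = 0,
    mode: str = "random",
    embedding: np.ndarray | None = None,
) -> np.ndarray:
    """Build aggregate membership: (n_aggregates, cells_per) cell indices.

    Random mode samples each aggregate's members without replacement when the
    population allows it (cells are reused freely *across* aggregates).  kNN
    mode seeds each aggregate at a random cell and adds its cells_per − 1
    nearest neighbors in the provided embedding.
    """
    rng = np.random.default_rng(seed)
    if n_cells == 0:
        raise ValueError("empty population")
    if mode == "random":
        replace = cells_per > n_cells
        return np.stack(
            [rng.choice(n_cells, size=cells_per, replace=replace) for _ in range(n_aggregates)]
        )
    if mode == "knn":
        if embedding is None:
            raise ValueError("knn mode requires an embedding")
        if cells_per > n_cells:
            raise ValueError("cells_per exceeds population in knn mode")
        nn = NearestNeighbors(n_neighbors=cells_per).fit(embedding)
        seeds = rng.integers(0, n_cells, size=n_aggregates)
        return nn.kneighbors(embedding[seeds], return_distance=False)
    raise ValueError(f"unknown mode {mode!r}")


def aggregate_means(matrix, membership: np.ndarray) -> np.ndarray:
    """Features × aggregates means given features × cells values."""
    X = sparse.csc_matrix(matrix, dtype=float)
    out = np.empty((X.shape[0], membership.shape[0]))
    for a, members in enumerate(membership):
        out[:, a] = np.asarray(X[:, members].mean(axis=1)).ravel()
    return out


def peak_gene_links(
    atac_agg: np.ndarray,
    peak_ids: list[str],
    peaks: pd.DataFrame,
    expr_agg: np.ndarray,
    gene_ids: list[str],
    genes: pd.DataFrame,
    lineage: str = "all",
    window: int = 250_000,
    r_min: float = 0.45,
    fdr_max: float = 1e-4,
) -> pd.DataFrame:
    """Correlate peak accessibility with gene expression across aggregates.

    Candidate pairs are peaks whose center lies within ±``window`` of a
    gene's TSS (same chromosome).  Retains pairs with r ≥ ``r_min`` and
    BH FDR < ``fdr_max``; the returned table also carries every tested pair
    with ``retained`` False for calibration work.
    """
    n_agg = atac_agg.shape[1]
    if expr_agg.shape[1] != n_agg:
        raise ValueError("aggregate counts differ between modalities")
    centers = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    peak_gr = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": peaks["chrom"],
                "Start": centers,
                "End": centers + 1,
                "peak_idx": np.arange(len(peaks)),
            }
        )
    )
    tss = genes["tss"].to_numpy()
    gene_gr = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": genes["chrom"],
                "Start": np.maximum(tss - window, 0),
                "End": tss + window + 1,
                "gene_idx": np.arange(len(genes)),
            }
        )
    )
    cand = gene_gr.join(peak_gr).df
    if len(cand) == 0:
        return pd.DataFrame(
            columns=["peak", "gene", "r", "p_raw", "fdr", "lineage", "distance", "retained"]
        )
    pi = cand["peak_idx"].to_numpy()
    gi = cand["gene_idx"].to_numpy()

    def standardized(M):
        mu = M.mean(axis=1, keepdims=True)
        sd = M.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            return np.where(sd > 0, (M - mu) / sd, np.nan)

    Zp = standardized(atac_agg)
    Zg = standardized(expr_agg)
    valid = np.isfinite(Zp[pi, 0]) & np.isfinite(Zg[gi, 0])
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.info("skipped %d zero-variance candidate pairs", n_skipped)
    pi, gi = pi[valid], gi[valid]
    r = (Zp[pi] * Zg[gi]).sum(axis=1) / n_agg
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        tstat = r * np.sqrt((n_agg - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(tstat), df=n_agg - 2)
    fdr = bh_adjust(p)
    dist = np.abs(centers[pi] - tss[gi])
    table = pd.DataFrame(
        {
            "peak": [peak_ids[i] for i in pi],
            "gene": [gene_ids[i] for i in gi],
            "r": r,
            "p_raw": p,
            "fdr": fdr,
            "lineage": lineage,
            "distance": dist,
            "retained": (r >= r_min) & (fdr < fdr_max),
        }
    )
    return table.sort_values(["fdr", "p_raw"]).reset_index(drop=True)


def hkmeans_links(activity: pd.DataFrame, k: int, max_iter: int = 100, tol: float = 1e-6) -> pd.Series:
    """hkmeans clustering: Ward cut at k initializes k-means refinement.

    Rows (links) are z-scored before clustering; deterministic given the
    inputs.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(activity):
        raise ValueError("k exceeds the number of links")
    M = activity.to_numpy(dtype=float)
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (M - mu) / sd
    ward = hierarchy.linkage(Z, method="ward")
    init_labels = hierarchy.fcluster(ward, t=k, criterion="maxclust") - 1
    centers = np.stack([Z[init_labels == c].mean(axis=0) for c in range(k)])
    km = KMeans(n_clusters=k, init=centers, n_init=1, max_iter=max_iter, tol=tol)
    labels = km.fit_predict(Z)
    return pd.Series(labels, index=activity.index, name="cluster")


def link_overlap_counts(
    linktables: dict[str, pd.DataFrame],
    consensus_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Venn-style sharing counts of link CREs and target genes across lineages.

    ``consensus_map`` resolves per-lineage peak ids to consensus ids before
    counting.  Rows: shared by all lineages, by exactly two, and specific to
    each lineage; columns for CREs and genes.
    """
    def resolve(p):
        return consensus_map.get(p, p) if consensus_map else p

    cre_sets = {
        lin: {resolve(p) for p in t.loc[t["retained"], "peak"]} for lin, t in linktables.items()
    }
    gene_sets = {lin: set(t.loc[t["retained"], "gene"]) for lin, t in linktables.items()}
    lineages = sorted(linktables)
    rows = []

    def counts(sets):
        membership: dict[str, int] = {}
        for lin in lineages:
            for x in sets[lin]:
                membership[x] = membership.get(x, 0) + 1
        n_all = sum(1 for v in membership.values() if v == len(lineages))
        n_two = sum(1 for v in membership.values() if v == 2) if len(lineages) != 2 else 0
        spec = {
            lin: sum(1 for x in sets[lin] if membership[x] == 1) for lin in lineages
        }
        return n_all, n_two, spec

    cre_all, cre_two, cre_spec = counts(cre_sets)
    gene_all, gene_two, gene_spec = counts(gene_sets)
    rows.append({"group": "shared_all", "cres": cre_all, "genes": gene_all})
    rows.append({"group": "shared_two", "cres": cre_two, "genes": gene_two})
    for lin in lineages:
        rows.append({"group": f"specific_{lin}", "cres": cre_spec[lin], "genes": gene_spec[lin]})
    return pd.DataFrame(rows)


def mean_conservation(
    track: pd.DataFrame,
    intervals: pd.DataFrame,
    groups: pd.Series | None = None,
) -> tuple[pd.Series, pd.DataFrame | None]:
    """Arithmetic mean of per-base conservation scores over each interval.

    ``track`` is bedGraph-like (chrom, start, end, score) with
    non-overlapping runs; bases not covered by the track score 0 and are
    flagged via the ``covered_fraction`` attribute on the result.  With
    ``groups`` (interval id → group label) a per-group summary is returned.
    """
    if (intervals["end"] <= intervals["start"]).any():
        raise ValueError("empty or inverted interval")
    means = pd.Series(np.nan, index=intervals.index, dtype=float)
    covered = pd.Series(0.0, index=intervals.index, dtype=float)
    for chrom, tr in track.groupby("chrom", sort=False):
        tr = tr.sort_values("start")
        ts = tr["start"].to_numpy()
        te = tr["end"].to_numpy()
        sc = tr["score"].to_numpy()
        # cumulative score mass up to each run boundary
        run_mass = sc * (te - ts)
        cum = np.concatenate([[0.0], np.cumsum(run_mass)])

        sub = intervals[intervals["chrom"] == chrom]
        for idx, row in sub.iterrows():
            s, e = int(row["start"]), int(row["end"])
            i0 = np.searchsorted(te, s, side="right")
            i1 = np.searchsorted(ts, e, side="left")
            total = 0.0
            nbases = 0
            if i1 > i0:
                total = cum[i1] - cum[i0]
                # correct partial first/last runs
                total -= sc[i0] * max(0, s - ts[i0])
                total -= sc[i1 - 1] * max(0, te[i1 - 1] - e)
                nbases = int(np.minimum(te[i0:i1], e).sum() - np.maximum(ts[i0:i1], s).sum())
            means[idx] = total / (e - s)
            covered[idx] = nbases / (e - s)
    outside = intervals.index[~intervals["chrom"].isin(track["chrom"].unique())]
    means[outside] = 0.0
    means.attrs["covered_fraction"] = covered
    summary = None
    if groups is not None:
        df = pd.DataFrame({"mean_score": means, "group": groups.reindex(intervals.index)})
        summary = (
            df.groupby("group")["mean_score"].agg(["mean", "median", "count"]).reset_index()
        )
    return means, summary
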