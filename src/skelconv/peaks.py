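"""Fixed-width peak finalization, consensus merging and genomic categorization.

Peak sets are plain :class:`pandas.DataFrame` objects with BED-like columns
(``chrom``, ``start``, ``end`` — 0-based half-open) plus ``summit`` (absolute
position), ``score`` (−log10 significance), ``origin`` (lineage label) and,
after :func:`classify_peaks`, ``category``.

The finalization scheme centers each called summit in a fixed-width window and
resolves overlaps greedily by significance ("iterative overlap"): the most
significant peak is kept and every peak overlapping it is discarded, repeated
until no overlaps remain.  The same logic merges per-lineage peak sets into a
consensus set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pyranges as pr
from scipy import stats

PEAK_COLUMNS = ["chrom", "start", "end", "summit", "score", "origin"]


def _iterative_overlap_keep(peaks: pd.DataFrame) -> np.ndarray:
    """Greedy significance-ranked overlap removal.

    Returns the positional indices (into ``peaks``) of retained rows.
    Equivalent to repeatedly keeping the highest-score peak and discarding all
    peaks overlapping it; ties broken by (chrom, start).
    """
    if peaks.empty:
        return np.array([], dtype=int)
    order = np.lexsort(
        (peaks["start"].to_numpy(), peaks["chrom"].to_numpy(), -peaks["score"].to_numpy())
    )
    kept: list[int] = []
    # per-chromosome sorted lists of kept intervals
    kept_by_chrom: dict[str, list[tuple[int, int]]] = {}
    import bisect

    chroms = peaks["chrom"].to_numpy()
    starts = peaks["start"].to_numpy()
    ends = peaks["end"].to_numpy()
    for i in order:
        ivs = kept_by_chrom.setdefault(chroms[i], [])
        s, e = int(starts[i]), int(ends[i])
        j = bisect.bisect_left(ivs, (s, e))
        overlaps = False
        if j < len(ivs) and ivs[j][0] < e:
            overlaps = True
        if j > 0 and ivs[j - 1][1] > s:
            overlaps = True
        if not overlaps:
            bisect.insort(ivs, (s, e))
            kept.append(i)
    return np.array(sorted(kept), dtype=int)


def finalize_peaks(
    summits: pd.DataFrame,
    width: int = 501,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Extend summits to fixed-width peaks and remove overlaps by significance.

    Parameters
    ----------
    summits
        DataFrame with columns ``chrom``, ``summit``, ``score`` and optionally
        ``origin``.
    width
        Final peak width in bp; must be odd so the summit is the exact center.
    chrom_sizes
        Mapping chromosome → length.  Summits whose window would spill past a
        chromosome boundary are dropped (preserving width homogeneity).
    """
    if width % 2 == 0:
        raise ValueError(f"peak width must be odd, got {width}")
    half = (width - 1) // 2
    df = summits.copy()
    df["start"] = df["summit"].astype(int) - half
    df["end"] = df["summit"].astype(int) + half + 1
    in_bounds = df["start"] >= 0
    if chrom_sizes is not None:
        sizes = df["chrom"].map(chrom_sizes)
        if sizes.isna().any():
            missing = sorted(df.loc[sizes.isna(), "chrom"].unique())
            raise ValueError(f"chromosomes missing from chrom_sizes: {missing}")
        in_bounds &= df["end"] <= sizes
    df = df.loc[in_bounds].reset_index(drop=True)
    keep = _iterative_overlap_keep(df)
    out = df.iloc[keep].reset_index(drop=True)
    if "origin" not in out.columns:
        out["origin"] = "."
    cols = PEAK_COLUMNS + [c for c in out.columns if c not in PEAK_COLUMNS]
    return out[cols]


def merge_origins(peaksets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Merge finalized per-lineage peak sets into a consensus set.

    The union of all peaks goes through the same iterative-overlap logic;
    each consensus peak records which origins contributed an overlapping peak
    (column ``origins``, comma-joined, sorted).
    """
    frames = []
    for origin, ps in peaksets.items():
        f = ps.copy()
        f["origin"] = origin
        frames.append(f)
    allp = pd.concat(frames, ignore_index=True)
    keep = _iterative_overlap_keep(allp)
    consensus = allp.iloc[keep].reset_index(drop=True)

    cons_gr = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": consensus["chrom"],
                "Start": consensus["start"],
                "End": consensus["end"],
                "cons_idx": np.arange(len(consensus)),
            }
        )
    )
    inp_gr = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": allp["chrom"],
                "Start": allp["start"],
                "End": allp["end"],
                "inp_origin": allp["origin"],
            }
        )
    )
    joined = cons_gr.join(inp_gr).df
    origins = (
        joined.groupby("cons_idx")["inp_origin"]
        .agg(lambda s: ",".join(sorted(set(s))))
        .reindex(np.arange(len(consensus)))
    )
    consensus["origins"] = origins.to_numpy()
    return consensus


def classify_peaks(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_window: tuple[int, int] = (-2000, 100),
) -> pd.DataFrame:
    """Assign each peak a genomic category: promoter > intronic > intergenic.

    A peak is *promoter* if it overlaps the strand-aware window
    ``[TSS + promoter_window[0], TSS + promoter_window[1]]`` of any gene,
    else *intronic* if it overlaps any gene body, else *intergenic*.

    ``genes`` needs columns ``chrom``, ``start``, ``end``, ``tss``, ``strand``.
    """
    up, down = promoter_window
    plus = genes["strand"] == "+"
    prom_start = np.where(plus, genes["tss"] + up, genes["tss"] - down)
    prom_end = np.where(plus, genes["tss"] + down + 1, genes["tss"] - up + 1)
    prom_start = np.maximum(prom_start, 0)

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
    prom_gr = pr.PyRanges(
        pd.DataFrame({"Chromosome": genes["chrom"], "Start": prom_start, "End": prom_end})
    )
    body_gr = pr.PyRanges(
        pd.DataFrame({"Chromosome": genes["chrom"], "Start": genes["start"], "End": genes["end"]})
    )
    in_prom = np.zeros(len(peaks), dtype=bool)
    hit = peak_gr.overlap(prom_gr).df
    if len(hit):
        in_prom[hit["peak_idx"].to_numpy()] = True
    in_body = np.zeros(len(peaks), dtype=bool)
    hit = peak_gr.overlap(body_gr).df
    if len(hit):
        in_body[hit["peak_idx"].to_numpy()] = True

    category = np.where(in_prom, "promoter", np.where(in_body, "intronic", "intergenic"))
    out = peaks.copy()
    out["category"] = category
    return out


def category_enrichment(
    dap_peaks: pd.DataFrame, consensus_peaks: pd.DataFrame
) -> pd.DataFrame:
    """Fold change and binomial p of DAP category fractions vs the consensus set.

    fold = (category fraction among DAPs) / (fraction among consensus peaks);
    p is a two-sided binomial test of the DAP category count against the
    consensus fraction.  Categories absent from the consensus get fold NaN and
    a ``flag``.
    """
    cats = ["promoter", "intronic", "intergenic"]
    n_dap = len(dap_peaks)
    n_cons = len(consensus_peaks)
    rows = []
    for cat in cats:
        k = int((dap_peaks["category"] == cat).sum())
        frac_cons = (consensus_peaks["category"] == cat).mean()
        if frac_cons == 0 or n_cons == 0:
            rows.append({"category": cat, "dap_count": k, "consensus_fraction": frac_cons,
                         "fold": np.nan, "p": np.nan, "flag": "empty_consensus_category"})
            continue
        fold = (k / n_dap) / frac_cons if n_dap else np.nan
        p = stats.binomtest(k, n_dap, frac_cons, alternative="two-sided").pvalue if n_dap else np.nan
        rows.append({"category": cat, "dap_count": k, "consensus_fraction": frac_cons,
                     "fold": fold, "p": p, "flag": ""})
    return pd.DataFrame(rows)


@dataclass
class PromoterDistalResult:
    """Cross-lineage accessibility similarity: promoter DAPs vs distal resamples."""

    promoter_rho: pd.DataFrame          # one row per lineage pair
    distal_rho: pd.DataFrame            # n_resamples rows per lineage pair
    mannwhitney_u: float
    mannwhitney_p: float
    flags: list[str] = field(default_factory=list)

    @property
    def promoter_median(self) -> float:
        return float(np.median(self.promoter_rho["rho"]))

    @property
    def distal_median(self) -> float:
        return float(np.median(self.distal_rho["rho"]))


def promoter_distal_similarity(
    dap_access: pd.DataFrame,
    categories: pd.Series,
    n_resamples: int = 80,
    seed: int = 0,
) -> PromoterDistalResult:
    """Compare cross-lineage accessibility agreement of promoter vs distal DAPs.

    ``dap_access`` holds pseudobulk accessibility of differential peaks, one
    column per lineage, indexed by peak id; ``categories`` assigns each peak
    'promoter' or a distal category ('intronic'/'intergenic').  For every
    lineage pair the Spearman rho across promoter-proximal peaks is computed,
    and ``n_resamples`` equal-size random draws of distal peaks give the
    reference distribution; the two pooled sets of coefficients are compared
    with a two-sided Mann–Whitney test.
    """
    if dap_access.shape[1] < 2:
        raise ValueError("need at least two lineages")
    cats = categories.reindex(dap_access.index)
    prom_ids = dap_access.index[cats == "promoter"]
    distal_ids = dap_access.index[cats.isin(["intronic", "intergenic"])]
    if len(prom_ids) == 0 or len(distal_ids) == 0:
        raise ValueError("both promoter and distal categories must be non-empty")
    flags = []
    replace = len(distal_ids) < len(prom_ids)
    if replace:
        flags.append("distal_sampled_with_replacement")
    rng = np.random.default_rng(seed)
    pairs = list(itertools.combinations(dap_access.columns, 2))

    prom_rows = []
    for a, b in pairs:
        rho = stats.spearmanr(dap_access.loc[prom_ids, a], dap_access.loc[prom_ids, b]).statistic
        prom_rows.append({"lineage_a": a, "lineage_b": b, "rho": rho})
    distal_rows = []
    for r in range(n_resamples):
        sample = rng.choice(distal_ids, size=len(prom_ids), replace=replace)
        for a, b in pairs:
            rho = stats.spearmanr(dap_access.loc[sample, a], dap_access.loc[sample, b]).statistic
            distal_rows.append({"resample": r, "lineage_a": a, "lineage_b": b, "rho": rho})
    prom_df = pd.DataFrame(prom_rows)
    dist_df = pd.DataFrame(distal_rows)
    pv = prom_df["rho"].to_numpy()
    dv = dist_df["rho"].to_numpy()
    if np.all(pv == pv[0]) and np.all(dv == pv[0]):
        u, p = np.nan, np.nan
        flags.append("degenerate_distributions")
    else:
        u, p = stats.mannwhitneyu(pv, dv, alternative="two-sided")
    return PromoterDistalResult(prom_df, dist_df, float(u), float(p), flags)
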