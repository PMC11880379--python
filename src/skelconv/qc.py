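"""Cell quality control for RNA and barcode QC for ATAC.

RNA filtering follows sample-relative rules: extreme total UMI counts
(> 4 × mean or < 0.2 × median), elevated mitochondrial fraction
(> median + 3 × MAD and > 0.1, spared when the cell's depth exceeds the
sample median), and a low genes-per-UMI ratio (< 0.15, spared for cells
detecting at least 2/3 of the sample maximum gene count).  Sample statistics
are computed once on the input population and frozen, which makes the filter
idempotent on its own output.

ATAC barcodes are filtered on fragments-in-peaks (closed range
1000–100,000), FRiP > 0.15, nucleosome signal < 4 and TSS enrichment > 2;
all comparisons strict except the stated closed range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass
class RnaQcThresholds:
    umi_high_factor: float = 4.0      # × mean total UMI
    umi_low_factor: float = 0.2       # × median total UMI
    mito_mad_factor: float = 3.0
    mito_floor: float = 0.1
    ratio_min: float = 0.15
    genes_spare_fraction: float = 2.0 / 3.0
    # alternative reading of the ratio-exception clause: spare cells with
    # FEWER than the fraction of max genes detected (the clause as printed)
    spare_low_genes: bool = False


@dataclass
class AtacQcThresholds:
    fragments_min: int = 1000
    fragments_max: int = 100_000
    frip_min: float = 0.15
    nucleosome_max: float = 4.0
    tss_min: float = 2.0


def rna_qc_metrics(counts, feature_ids: list[str], mito_gene_ids: list[str]) -> pd.DataFrame:
    """Per-cell totals, genes detected, mitochondrial fraction, genes/UMI."""
    X = sparse.csc_matrix(counts)
    total = np.asarray(X.sum(axis=0)).ravel()
    genes = np.asarray((X > 0).sum(axis=0)).ravel()
    mito_set = set(mito_gene_ids)
    unknown = mito_set - set(feature_ids)
    if unknown:
        raise ValueError(f"mito genes not in features: {sorted(unknown)[:5]}")
    rows = [i for i, f in enumerate(feature_ids) if f in mito_set]
    mito = np.asarray(X[rows].sum(axis=0)).ravel() if rows else np.zeros_like(total, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / total, 0.0)
        ratio = np.where(total > 0, genes / total, 0.0)
    return pd.DataFrame(
        {
            "total_umi": total,
            "genes_detected": genes,
            "mito_fraction": mito_frac,
            "genes_per_umi": ratio,
        }
    )


def qc_filter_rna(
    counts,
    feature_ids: list[str],
    cell_ids: list[str],
    mito_gene_ids: list[str],
    thresholds: RnaQcThresholds | None = None,
    frozen_stats: dict | None = None,
) -> tuple[list[str], pd.DataFrame, pd.DataFrame]:
    """Apply the RNA cell filters; returns (kept ids, metrics, per-rule flags).

    Sample-level statistics (mean/median/MAD) are computed once on the input
    population and reported in ``flags.attrs['frozen_stats']``; passing them
    back via ``frozen_stats`` re-applies the filter with the original sample
    statistics, which makes filtering idempotent.  The MAD is the unscaled
    median absolute deviation.
    """
    th = thresholds or RnaQcThresholds()
    X = sparse.csc_matrix(counts)
    if X.shape[1] == 0:
        raise ValueError("zero cells")
    if X.nnz == 0:
        raise ValueError("all-zero count matrix")
    metrics = rna_qc_metrics(X, feature_ids, mito_gene_ids)
    metrics.index = cell_ids

    total = metrics["total_umi"].to_numpy()
    mito = metrics["mito_fraction"].to_numpy()
    genes = metrics["genes_detected"].to_numpy()
    ratio = metrics["genes_per_umi"].to_numpy()

    if frozen_stats is not None:
        mean_total = frozen_stats["mean_total"]
        med_total = frozen_stats["median_total"]
        med_mito = frozen_stats["median_mito"]
        mad_mito = frozen_stats["mad_mito"]
        max_genes = frozen_stats["max_genes"]
    else:
        mean_total = total.mean()
        med_total = np.median(total)
        med_mito = np.median(mito)
        mad_mito = np.median(np.abs(mito - med_mito))
        max_genes = genes.max()

    umi_high = total > th.umi_high_factor * mean_total
    umi_low = total < th.umi_low_factor * med_total
    mito_high = (
        (mito > med_mito + th.mito_mad_factor * mad_mito)
        & (mito > th.mito_floor)
        & ~(total > med_total)
    )
    if th.spare_low_genes:
        spared = genes < th.genes_spare_fraction * max_genes
    else:
        spared = genes >= th.genes_spare_fraction * max_genes
    ratio_low = (ratio < th.ratio_min) & ~spared

    flags = pd.DataFrame(
        {
            "umi_high": umi_high,
            "umi_low": umi_low,
            "mito_high": mito_high,
            "ratio_low": ratio_low,
        },
        index=cell_ids,
    )
    removed = flags.any(axis=1)
    kept = [c for c, r in zip(cell_ids, removed) if not r]
    flags.attrs["frozen_stats"] = {
        "mean_total": float(mean_total),
        "median_total": float(med_total),
        "median_mito": float(med_mito),
        "mad_mito": float(mad_mito),
        "max_genes": int(max_genes),
        "ratio_definition": "genes_detected / total_umi",
    }
    return kept, metrics, flags


def _overlaps_intervals(starts: np.ndarray, ends: np.ndarray, chroms: np.ndarray,
                        iv: pd.DataFrame) -> np.ndarray:
    """Interval overlap of [start, end) records against disjoint sorted intervals."""
    hit = np.zeros(len(starts), dtype=bool)
    for chrom, sub in iv.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        ivs = sub["start"].to_numpy()
        ive = sub["end"].to_numpy()
        mask = chroms == chrom
        s, e = starts[mask], ends[mask]
        # first interval whose end is beyond the record start
        j = np.searchsorted(ive, s, side="right")
        ok = (j < len(ivs)) & (ivs[np.clip(j, 0, len(ivs) - 1)] < e)
        hit[mask] = ok
    return hit


def _count_in_intervals(positions: np.ndarray, chroms: np.ndarray,
                        iv: pd.DataFrame) -> np.ndarray:
    """Boolean membership of positions in a set of disjoint intervals."""
    hit = np.zeros(len(positions), dtype=bool)
    for chrom, sub in iv.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        mask = chroms == chrom
        pos = positions[mask]
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[np.clip(j, 0, len(ends) - 1)])
        hit[mask] = ok
    return hit


def _merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    out = []
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cs, ce = None, None
        for s, e in zip(sub["start"], sub["end"]):
            if cs is None:
                cs, ce = s, e
            elif s <= ce:
                ce = max(ce, e)
            else:
                out.append((chrom, cs, ce))
                cs, ce = s, e
        if cs is not None:
            out.append((chrom, cs, ce))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def compute_atac_metrics(
    fragments: pd.DataFrame,
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    tss_core: int = 50,
    tss_flank: tuple[int, int] = (1901, 2000),
    pseudocount: float = 0.1,
    genome_size: int | None = None,
) -> pd.DataFrame:
    """Per-barcode ATAC QC metrics from a fragments table.

    frip = fragments whose interval overlaps any peak / total fragments.
    nucleosome_signal =
    count(147 ≤ length ≤ 294) / max(1, count(length < 147)).  tss_enrichment
    = mean insertion coverage within ±``tss_core`` bp of TSSs over the mean
    coverage in the ±(1901–2000) bp flanks; ``pseudocount`` (in units of the
    barcode's genome-wide mean insertion rate, so the metric is depth-scale
    free) is added to both rates.  ``genome_size`` defaults to the span of
    the observed fragments.  Barcodes with zero fragments get zero metrics
    and a flag.
    """
    frag = fragments
    lengths = (frag["end"] - frag["start"]).to_numpy()
    chroms = frag["chrom"].to_numpy()
    barcodes = frag["barcode"].to_numpy()

    peak_iv = _merge_intervals(peaks[["chrom", "start", "end"]])
    starts = frag["start"].to_numpy()
    ends = frag["end"].to_numpy()
    in_peak = _overlaps_intervals(starts, ends, chroms, peak_iv)

    tss = genes["tss"].to_numpy()
    gchrom = genes["chrom"].to_numpy()
    core = _merge_intervals(pd.DataFrame({
        "chrom": gchrom, "start": np.maximum(tss - tss_core, 0), "end": tss + tss_core + 1,
    }))
    lo, hi = tss_flank
    flank = _merge_intervals(pd.DataFrame({
        "chrom": np.concatenate([gchrom, gchrom]),
        "start": np.concatenate([np.maximum(tss - hi, 0), tss + lo]),
        "end": np.concatenate([np.maximum(tss - lo + 1, 0), tss + hi + 1]),
    }))
    core_bases = float((core["end"] - core["start"]).sum())
    flank_bases = float((flank["end"] - flank["start"]).sum())

    # insertions: both ends of each fragment
    ins_pos = np.concatenate([starts, ends - 1])
    ins_chrom = np.concatenate([chroms, chroms])
    ins_bc = np.concatenate([barcodes, barcodes])
    in_core = _count_in_intervals(ins_pos, ins_chrom, core)
    in_flank = _count_in_intervals(ins_pos, ins_chrom, flank)

    df = pd.DataFrame({"barcode": barcodes, "in_peak": in_peak,
                       "nfr": lengths < 147,
                       "mono": (lengths >= 147) & (lengths <= 294)})
    agg = df.groupby("barcode").agg(
        n_fragments=("in_peak", "size"),
        fragments_in_peaks=("in_peak", "sum"),
        n_nfr=("nfr", "sum"),
        n_mono=("mono", "sum"),
    )
    ins = pd.DataFrame({"barcode": ins_bc, "core": in_core, "flank": in_flank})
    ins_agg = ins.groupby("barcode").agg(core=("core", "sum"), flank=("flank", "sum"))
    agg = agg.join(ins_agg, how="left").fillna(0)

    frip = agg["fragments_in_peaks"] / agg["n_fragments"]
    nucleosome = agg["n_mono"] / np.maximum(1, agg["n_nfr"])
    if genome_size is None:
        genome_size = int(frag.groupby("chrom")["end"].max().sum())
    global_rate = 2.0 * agg["n_fragments"] / max(genome_size, 1)
    pc = pseudocount * global_rate
    core_cov = agg["core"] / core_bases + pc
    flank_cov = agg["flank"] / flank_bases + pc
    tss_enr = core_cov / flank_cov
    out = pd.DataFrame(
        {
            "fragments_in_peaks": agg["fragments_in_peaks"].astype(int),
            "frip": frip,
            "nucleosome_signal": nucleosome,
            "tss_enrichment": tss_enr,
            "flag": "",
        }
    )
    return out


def qc_filter_atac(
    metrics: pd.DataFrame, thresholds: AtacQcThresholds | None = None
) -> list:
    """Barcodes passing all four ATAC thresholds."""
    th = thresholds or AtacQcThresholds()
    keep = (
        (metrics["fragments_in_peaks"] >= th.fragments_min)
        & (metrics["fragments_in_peaks"] <= th.fragments_max)
        & (metrics["frip"] > th.frip_min)
        & (metrics["nucleosome_signal"] < th.nucleosome_max)
        & (metrics["tss_enrichment"] > th.tss_min)
    )
    return list(metrics.index[keep])
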