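"""End-to-end pipeline: sim → qc → pseudobulk → differential → peaks →
trajectory → motifs → links, with a machine-readable report.

Each stage is a function taking the cohort plus accumulated state, so the
stages can be run individually (the CLI subcommands map onto them) or
chained by :func:`run_pipeline`.  The report JSON carries every stage's
headline outputs and is the single integration surface.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential, links, motifs, peaks as peaks_mod, pseudobulk, qc, trajectory
from .sim import SimConfig, SyntheticCohort, simulate_cohort

logger = logging.getLogger("skelconv")

REPORT_SCHEMA_VERSION = 1
STAGES = ["sim", "qc", "pseudobulk", "differential", "peaks", "trajectory",
          "motifs", "links"]


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration; unknown keys are rejected on load."""

    seed: int = 0
    outdir: str = "skelconv_out"
    bundle_dir: str | None = None          # read inputs instead of simulating
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    # marker-test thresholds (broad/fine fold-change conventions)
    de_logfc_min: float = 0.25
    da_logfc_min: float = 0.25
    alpha: float = 0.05
    min_pct: float = 0.1
    adjust: str = "bonferroni"
    # peaks
    peak_width: int = 501
    promoter_window: tuple[int, int] = (-2000, 100)
    n_resamples: int = 80
    # trajectory
    n_bins: int = 20
    n_points: int = 40
    transfer_k: int = 10
    # motifs
    trim_min_ic: float = 0.25
    dedup_threshold: float = 0.8
    deviation_background: int = 50
    deviation_cells: int = 500
    # links
    n_aggregates: int = 500
    cells_per_aggregate: int = 100
    link_window: int = 250_000
    link_r_min: float = 0.45
    link_fdr_max: float = 1e-4
    hkmeans_k: int = 4

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "promoter_window" in d:
            d["promoter_window"] = tuple(d["promoter_window"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def sim_config(self) -> SimConfig:
        overrides = dict(self.sim)
        for key in ("n_module_genes", "depth_lognormal_params", "motif_lengths",
                    "conservation_levels"):
            if key in overrides:
                overrides[key] = tuple(overrides[key])
        overrides.setdefault("seed", self.seed)
        return SimConfig(**overrides)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _json_safe(x):
    if isinstance(x, dict):
        return {str(k): _json_safe(v) for k, v in x.items()}
    if isinstance(x, (list, tuple, set)):
        return [_json_safe(v) for v in x]
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating, float)):
        v = float(x)
        return v if np.isfinite(v) else None
    if isinstance(x, np.bool_):
        return bool(x)
    if isinstance(x, pd.DataFrame):
        return _json_safe(x.to_dict(orient="records"))
    if isinstance(x, (np.ndarray, pd.Series)):
        return _json_safe(list(x))
    return x


# --------------------------------------------------------------------------
# stages


def stage_qc(cohort: SyntheticCohort, cfg: PipelineConfig, state: dict) -> dict:
    mito = [g for g in cohort.rna.feature_ids if g.startswith("MT-")]
    kept_rna, rna_metrics, rna_flags = qc.qc_filter_rna(
        cohort.rna.X, cohort.rna.feature_ids, list(cohort.rna.cells.index), mito
    )
    atac_metrics = qc.compute_atac_metrics(cohort.fragments, cohort.peaks, cohort.genes)
    kept_atac = qc.qc_filter_atac(atac_metrics)
    state["kept_rna"] = kept_rna
    state["kept_atac"] = kept_atac
    state["atac_metrics"] = atac_metrics
    return {
        "rna_cells_in": int(cohort.rna.X.shape[1]),
        "rna_cells_kept": len(kept_rna),
        "rna_rule_counts": {c: int(rna_flags[c].sum()) for c in rna_flags.columns},
        "atac_barcodes_in": int(len(atac_metrics)),
        "atac_barcodes_kept": len(kept_atac),
        "median_frip": float(atac_metrics["frip"].median()),
        "median_tss_enrichment": float(atac_metrics["tss_enrichment"].median()),
    }


def _subset(cm, keep_ids):
    pos = {c: i for i, c in enumerate(cm.cells.index)}
    cols = [pos[c] for c in keep_ids]
    from .sim import CellMatrix

    return CellMatrix(cm.X[:, cols].tocsr(), list(cm.feature_ids),
                      cm.cells.iloc[cols].copy())


def stage_pseudobulk(cohort: SyntheticCohort, cfg: PipelineConfig, state: dict) -> dict:
    rna = _subset(cohort.rna, state.get("kept_rna", list(cohort.rna.cells.index)))
    norm = pseudobulk.normalize_log(rna.X)
    state["rna_kept"] = rna
    state["rna_norm"] = norm
    hvg = pseudobulk.select_hvg(norm, rna.feature_ids)
    state["hvg"] = hvg
    imm, red = cohort.truth.module_genes
    scores = {}
    for name, gene_set in (("IMM", sorted(imm)), ("RED", sorted(red))):
        if gene_set:
            scores[name] = pseudobulk.score_module(
                norm, rna.feature_ids, gene_set, seed=cfg.seed
            )
    labels = rna.cells["lineage"] + "_" + rna.cells["cluster"]
    profile = pseudobulk.pseudobulk_means(norm, rna.feature_ids, labels)
    state["profile"] = profile
    state["group_labels"] = labels
    out = {"n_hvg": len(hvg), "groups": list(profile.columns)}
    if scores:
        ec_mask = (rna.cells["cluster"] == "EC").to_numpy()
        out["module_score_ec_minus_pc"] = {
            name: float(np.mean(s[ec_mask]) - np.mean(s[rna.cells["cluster"] == "PC"]))
            for name, s in scores.items()
        }
    return out


def stage_differential(cohort: SyntheticCohort, cfg: PipelineConfig, state: dict) -> dict:
    rna = state["rna_kept"]
    norm = state["rna_norm"]
    marker_tables = {}
    for lin in sorted(rna.cells["lineage"].unique()):
        in_lin = (rna.cells["lineage"] == lin).to_numpy()
        sub = norm[:, in_lin]
        cells = rna.cells.loc[in_lin]
        mask = (cells["cluster"] == "EC").to_numpy()
        depth = np.log(np.asarray(rna.X[:, in_lin].sum(axis=0)).ravel())
        stage_num = cells["stage"].str.slice(1).astype(int).to_numpy()
        latents = np.column_stack([depth, stage_num])
        marker_tables[lin] = differential.lr_markers(
            sub, rna.feature_ids, mask, latents,
            min_pct=cfg.min_pct, logfc_min=cfg.de_logfc_min,
            alpha=cfg.alpha, adjust=cfg.adjust,
        )
    state["marker_tables"] = marker_tables
    shared = differential.common_markers(list(marker_tables.values()))
    state["common_chondrogenic"] = shared

    # differential accessibility per lineage on the paired ATAC cells
    atac = cohort.atac
    danorm = pseudobulk.normalize_log(atac.X)
    state["atac_norm"] = danorm
    dap_tables = {}
    for lin in sorted(atac.cells["lineage"].unique()):
        in_lin = (atac.cells["lineage"] == lin).to_numpy()
        cells = atac.cells.loc[in_lin]
        mask = (cells["cluster"] == "EC").to_numpy()
        depth = np.log(np.asarray(atac.X[:, in_lin].sum(axis=0)).ravel())
        stage_num = cells["stage"].str.slice(1).astype(int).to_numpy()
        dap_tables[lin] = differential.lr_markers(
            danorm[:, in_lin], atac.feature_ids, mask,
            np.column_stack([depth, stage_num]),
            min_pct=cfg.min_pct, logfc_min=cfg.da_logfc_min,
            alpha=cfg.alpha, adjust=cfg.adjust,
        )
    state["dap_tables"] = dap_tables

    de_union = sorted(set().union(*[set(t.index[t["pass"]]) for t in marker_tables.values()]))
    state["de_union"] = de_union
    tf_features = sorted(set().union(*cohort.truth.lineage_tfs.values())
                         & set(state["rna_kept"].feature_ids))
    state["tf_features"] = tf_features

    module = set().union(*cohort.truth.module_genes)
    recovered = len(shared & module) / len(module) if module else np.nan
    report = {
        "n_de_per_lineage": {lin: int(t["pass"].sum()) for lin, t in marker_tables.items()},
        "n_common_chondrogenic": len(shared),
        "module_recovered_fraction": recovered,
        "n_dap_per_lineage": {lin: int(t["pass"].sum()) for lin, t in dap_tables.items()},
    }

    # co-clustering verdicts (the Fig 2a-vs-2b contrast)
    profile = state["profile"]
    ec_groups = {g for g in profile.columns if g.endswith("_EC")}
    verdicts = {}
    if len(de_union) >= 3:
        cc = pseudobulk.correlate_and_cluster(profile, de_union)
        verdicts["ec_exclusive_clade_de_features"] = cc.is_exclusive_clade(ec_groups)
        state["cc_de"] = cc
    if len(tf_features) >= 3:
        cc_tf = pseudobulk.correlate_and_cluster(profile, tf_features)
        lineage_clades = all(
            cc_tf.is_exclusive_clade({g for g in profile.columns if g.startswith(lin + "_")})
            for lin in sorted(state["rna_kept"].cells["lineage"].unique())
        )
        verdicts["lineage_clades_tf_features"] = lineage_clades
        state["cc_tf"] = cc_tf
    report["coclustering"] = verdicts
    return report


def stage_peaks(cohort: SyntheticCohort, cfg: PipelineConfig, state: dict) -> dict:
    summits = cohort.peaks[["chrom", "summit", "score", "origin"]]
    by_origin = {
        origin: peaks_mod.finalize_peaks(grp, cfg.peak_width, cohort.genome_sizes)
        for origin, grp in summits.groupby("origin")
    }
    consensus = peaks_mod.merge_origins(by_origin)
    consensus = peaks_mod.classify_peaks(consensus, cohort.genes, cfg.promoter_window)
    classified = peaks_mod.classify_peaks(cohort.peaks, cohort.genes, cfg.promoter_window)
    state["peaks_classified"] = classified

    dap_tables = state["dap_tables"]
    dap_ids = sorted(set().union(*[set(t.index[t["pass"]]) for t in dap_tables.values()]))
    state["dap_ids"] = dap_ids
    dap_peaks = classified.set_index("peak_id").loc[dap_ids].reset_index()
    enrich = peaks_mod.category_enrichment(dap_peaks, consensus)

    # cross-lineage EC accessibility of DAPs: promoter-proximal vs distal
    atac = cohort.atac
    danorm = state["atac_norm"]
    ec = atac.cells["cluster"] == "EC"
    cols = {}
    for lin in sorted(atac.cells["lineage"].unique()):
        m = (ec & (atac.cells["lineage"] == lin)).to_numpy()
        cols[lin] = np.asarray(danorm[:, np.flatnonzero(m)].mean(axis=1)).ravel()
    access = pd.DataFrame(cols, index=atac.feature_ids).loc[dap_ids]
    cats = classified.set_index("peak_id")["category"]
    pd_res = peaks_mod.promoter_distal_similarity(
        access, cats, n_resamples=cfg.n_resamples, seed=cfg.seed
    )
    state["promoter_distal"] = pd_res
    return {
        "n_consensus_peaks": len(consensus),
        "peak_width_uniform": bool(((consensus["end"] - consensus["start"]) == cfg.peak_width).all()),
        "category_enrichment": enrich,
        "promoter_median_rho": pd_res.promoter_median,
        "distal_median_rho": pd_res.distal_median,
        "promoter_gt_distal": pd_res.promoter_median > pd_res.distal_median,
    }


def stage_trajectory(cohort: SyntheticCohort, cfg: PipelineConfig, state: dict) -> dict:
    rna = state["rna_kept"]
    norm = state["rna_norm"]
    module = sorted(set().union(*cohort.truth.module_genes))
    tfs = sorted(set().union(*cohort.truth.lineage_tfs.values()))
    feats = module + tfs
    bins = {}
    for lin in sorted(rna.cells["lineage"].unique()):
        m = (rna.cells["lineage"] == lin).to_numpy()
        bins[lin] = trajectory.bin_pseudotime(
            norm[:, np.flatnonzero(m)], rna.feature_ids,
            rna.cells.loc[m, "pseudotime"].to_numpy(), cfg.n_bins,
        )
    state["bins"] = bins
    lineages = sorted(bins)
    alignments = {}
    for i in range(len(lineages)):
        for j in range(i + 1, len(lineages)):
            a, b = lineages[i], lineages[j]
            res = trajectory.align_trajectories(bins[a], bins[b], module, cfg.n_points)
            alignments[f"{a}~{b}"] = {
                "mean_cost": res.mean_cost,
                "n_unmatched_a": len(res.unmatched_a[0]) + len(res.unmatched_a[1]),
                "n_unmatched_b": len(res.unmatched_b[0]) + len(res.unmatched_b[1]),
            }

    activity, act_genes = trajectory.gene_activity(cohort.atac.X, cohort.peaks, cohort.genes)
    act_norm = pseudobulk.normalize_log(activity)
    transferred = trajectory.transfer_pseudotime(
        norm, rna.feature_ids, rna.cells["pseudotime"].to_numpy(),
        act_norm, act_genes, k=cfg.transfer_k,
    )
    state["atac_pseudotime"] = pd.Series(transferred, index=cohort.atac.cells.index)
    paired = cohort.truth.paired_cells or {}
    truth_t = []
    est_t = []
    for a_cell, t_hat in state["atac_pseudotime"].items():
        r_cell = paired.get(a_cell)
        if r_cell is not None:
            truth_t.append(cohort.truth.true_pseudotime[r_cell])
            est_t.append(t_hat)
    from scipy import stats as sstats

    rho = sstats.spearmanr(truth_t, est_t).statistic if len(truth_t) > 2 else np.nan

    # planted DAP accessibility along the transferred ATAC pseudotime
    danorm = state["atac_norm"]
    dap_rise = {}
    for lin in lineages:
        own = sorted(cohort.truth.lineage_daps.get(lin, []))
        if not own:
            continue
        m = (cohort.atac.cells["lineage"] == lin).to_numpy()
        tb = trajectory.bin_pseudotime(
            danorm[:, np.flatnonzero(m)], cohort.atac.feature_ids,
            state["atac_pseudotime"][m].to_numpy(), 10,
        )
        prof = tb.means.loc[own].mean(axis=0).to_numpy()
        dap_rise[lin] = float(prof[-1] - prof[0])
    return {
        "alignments": alignments,
        "transfer_spearman_vs_truth": float(rho),
        "dap_rise_along_own_pseudotime": dap_rise,
    }


def stage_motifs(cohort: SyntheticCohort, cfg: PipelineConfig, state: dict) -> dict:
    denovo = [motifs.trim_pwm(p, cfg.trim_min_ic) for p in cohort.pwms["denovo"]]
    kept, redundancy = motifs.dedup_motifs(denovo, cfg.dedup_threshold)

    hits = cohort.hit_matrix
    atac = cohort.atac
    rng = np.random.default_rng(cfg.seed)
    n_cells = atac.X.shape[1]
    sub = np.sort(rng.choice(n_cells, size=min(cfg.deviation_cells, n_cells), replace=False))
    dev = motifs.motif_deviations(
        atac.X[:, sub], list(atac.feature_ids),
        [atac.cells.index[i] for i in sub], hits,
        cohort.peaks.set_index("peak_id")["gc"],
        n_background=cfg.deviation_background, seed=cfg.seed,
    )
    state["deviations"] = dev

    # lineage-specificity of planted TF motif activities in EC cells
    cells = atac.cells.iloc[sub]
    ec_by_lin = {
        lin: ((cells["cluster"] == "EC") & (cells["lineage"] == lin)).to_numpy()
        for lin in sorted(cells["lineage"].unique())
    }
    own_highest = 0
    n_eval = 0
    for pwm in cohort.pwms["denovo"]:
        lin = pwm.context.get("lineage")
        if lin not in ec_by_lin or pwm.name not in dev.z.index:
            continue
        z = dev.z.loc[pwm.name].to_numpy()
        means = {l: np.nanmean(z[m]) for l, m in ec_by_lin.items() if m.any()}
        if len(means) < 2:
            continue
        n_eval += 1
        if max(means, key=means.get) == lin:
            own_highest += 1

    rna = state["rna_kept"]
    rna_norm_df = pd.DataFrame(
        np.asarray(state["rna_norm"].todense()),
        index=rna.feature_ids, columns=rna.cells.index,
    )
    paired = cohort.truth.paired_cells or {}
    dev_paired = dev.z.copy()
    dev_paired.columns = [paired.get(c, c) for c in dev.z.columns]
    shared_cells = [c for c in dev_paired.columns if c in rna_norm_df.columns]
    annotation = motifs.annotate_motifs(
        cohort.pwms["denovo"], cohort.pwms["reference"],
        rna_norm_df[shared_cells], dev_paired[shared_cells],
        cohort.pwms["tf_of_reference"], seed=cfg.seed,
    )
    best = annotation[annotation["rank"] == 1].set_index("motif")["tf"]
    correct = sum(
        1 for p in cohort.pwms["denovo"]
        if best.get(p.name) == p.context.get("source_tf")
    )

    by_tf: dict[str, list] = {}
    for p in cohort.pwms["context"]:
        by_tf.setdefault(p.context["source_tf"], []).append(p)
    ctx_df, u, pval = motifs.context_similarity_groups(by_tf, cfg.trim_min_ic)
    med = ctx_df.groupby("group")["similarity"].median()
    state["annotation"] = annotation
    return {
        "n_denovo": len(denovo),
        "n_nonredundant": len(kept),
        "deviation_own_lineage_highest": own_highest,
        "deviation_motifs_evaluated": n_eval,
        "annotation_correct": int(correct),
        "annotation_total": len(cohort.pwms["denovo"]),
        "context_similarity_median": {k: float(v) for k, v in med.items()},
        "context_mannwhitney_p": pval,
    }


def stage_links(cohort: SyntheticCohort, cfg: PipelineConfig, state: dict) -> dict:
    atac = cohort.atac
    danorm = state["atac_norm"]
    rna_norm_all = pseudobulk.normalize_log(cohort.rna.X)
    paired = cohort.truth.paired_cells or {}
    rna_pos = {c: i for i, c in enumerate(cohort.rna.cells.index)}

    # aggregates of *neighboring* cells (kNN in pseudotime space): random
    # pooling would average out trajectory variation and with it every
    # dynamics-driven link
    atac_t = state.get("atac_pseudotime")
    if atac_t is None:
        atac_t = atac.cells["pseudotime"]
    tables = {}
    for li, lin in enumerate(sorted(atac.cells["lineage"].unique())):
        m = np.flatnonzero((atac.cells["lineage"] == lin).to_numpy())
        membership = links.aggregate_cells(
            len(m), cfg.n_aggregates, cfg.cells_per_aggregate, seed=cfg.seed + li,
            mode="knn", embedding=atac_t.to_numpy()[m][:, None],
        )
        atac_agg = links.aggregate_means(danorm[:, m], membership)
        rna_cols = np.array([rna_pos[paired[atac.cells.index[i]]] for i in m])
        expr_agg = links.aggregate_means(rna_norm_all[:, rna_cols], membership)
        tables[lin] = links.peak_gene_links(
            atac_agg, list(atac.feature_ids), cohort.peaks,
            expr_agg, cohort.rna.feature_ids, cohort.genes,
            lineage=lin, window=cfg.link_window,
            r_min=cfg.link_r_min, fdr_max=cfg.link_fdr_max,
        )
    state["link_tables"] = tables

    found = set()
    for t in tables.values():
        found |= set(map(tuple, t.loc[t["retained"], ["peak", "gene"]].to_numpy()))
    truth_links = cohort.truth.planted_links
    recall = len(found & truth_links) / len(truth_links) if truth_links else np.nan
    precision = len(found & truth_links) / len(found) if found else np.nan

    overlap = links.link_overlap_counts(tables)

    retained_peaks = sorted({p for p, _ in found})
    summary = None
    if retained_peaks:
        # conservation of link CREs grouped by cross-lineage sharing
        cre_sets = {
            lin: set(t.loc[t["retained"], "peak"]) for lin, t in tables.items()
        }
        n_lin = len(cre_sets)
        group = {}
        for p in retained_peaks:
            k = sum(p in s for s in cre_sets.values())
            group[p] = "common" if k == n_lin else ("shared_two" if k >= 2 else "specific")
        iv = cohort.peaks.set_index("peak_id").loc[retained_peaks, ["chrom", "start", "end"]]
        _, summary = links.mean_conservation(
            cohort.conservation, iv, pd.Series(group)
        )
        hk_input = pd.DataFrame(
            {
                lin: tables[lin].set_index(["peak", "gene"])["r"]
                .reindex(pd.MultiIndex.from_tuples(sorted(found)))
                for lin in tables
            }
        ).fillna(0.0)
        hk = links.hkmeans_links(hk_input, min(cfg.hkmeans_k, max(2, len(hk_input) - 1))) \
            if len(hk_input) >= 3 else None
    else:
        hk = None
    out = {
        "n_links_per_lineage": {lin: int(t["retained"].sum()) for lin, t in tables.items()},
        "recall_vs_planted": recall,
        "precision_vs_planted": precision,
        "overlap_counts": overlap,
    }
    if summary is not None:
        out["conservation_by_sharing"] = summary
        means = summary.set_index("group")["mean"]
        if "common" in means.index and "specific" in means.index:
            out["conservation_common_gt_specific"] = bool(
                means["common"] > means["specific"]
            )
    if hk is not None:
        out["hkmeans_cluster_sizes"] = hk.value_counts().sort_index().tolist()
    return out


def run_pipeline(config: PipelineConfig, cohort: SyntheticCohort | None = None) -> dict:
    """Execute the configured stages and return (and write) the report."""
    t0 = time.time()
    logger.info("pipeline start: seed=%d config=%s", config.seed, config.digest())
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "config_digest": config.digest(),
        "stages": {},
    }
    state: dict = {}
    deps = {
        "pseudobulk": [], "differential": ["pseudobulk"],
        "peaks": ["differential"], "trajectory": ["differential"],
        "motifs": ["pseudobulk"], "links": ["differential"],
    }
    if cohort is None:
        if "sim" in config.stages:
            cohort = simulate_cohort(config.sim_config())
            report["stages"]["sim"] = {
                "n_rna_cells": int(cohort.rna.X.shape[1]),
                "n_genes": len(cohort.rna.feature_ids),
                "n_peaks": len(cohort.peaks),
            }
        elif config.bundle_dir:
            from .io import read_bundle

            cohort = read_bundle(config.bundle_dir)
            report["stages"]["sim"] = {"loaded_from": str(config.bundle_dir)}
        else:
            raise ValueError("no cohort: enable the sim stage or set bundle_dir")

    funcs = {
        "qc": stage_qc, "pseudobulk": stage_pseudobulk,
        "differential": stage_differential, "peaks": stage_peaks,
        "trajectory": stage_trajectory, "motifs": stage_motifs,
        "links": stage_links,
    }
    done = set(report["stages"])
    for stage in [s for s in STAGES if s in config.stages and s != "sim"]:
        missing = [d for d in deps.get(stage, []) if d not in done]
        if missing:
            raise RuntimeError(f"stage '{stage}' requires disabled stage(s) {missing}")
        logger.info("stage %s ...", stage)
        try:
            report["stages"][stage] = _json_safe(funcs[stage](cohort, config, state))
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        done.add(stage)
    report["elapsed_seconds"] = round(time.time() - t0, 2)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    logger.info("pipeline done in %.1fs", report["elapsed_seconds"])
    return report
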