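"""Standard-format readers and writers for cohort bundles.

A bundle directory holds Matrix Market count matrices with barcode/feature
TSVs, BED peaks, a fragments TSV, JASPAR-format PFM files (written and read
through Biopython), a bedGraph conservation track, a gene annotation table
and a ground-truth JSON.  All intervals are 0-based half-open on disk and in
memory.
"""

from __future__ import annotations

import json
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from scipy import io as spio
from scipy import sparse

from .motifs import PWM
from .sim import CellMatrix, GroundTruth, SimConfig, SyntheticCohort

BED_COLUMNS = ["chrom", "start", "end", "peak_id", "score_i", "strand",
               "summit_offset", "origin", "category"]


def write_matrix(directory: Path, prefix: str, cm: CellMatrix) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(directory / f"{prefix}_matrix.mtx"), sparse.coo_matrix(cm.X))
    pd.Series(cm.feature_ids).to_csv(directory / f"{prefix}_features.tsv",
                                     sep="\t", index=False, header=False)
    cm.cells.to_csv(directory / f"{prefix}_barcodes.tsv", sep="\t")


def read_matrix(directory: Path, prefix: str) -> CellMatrix:
    X = sparse.csr_matrix(spio.mmread(str(directory / f"{prefix}_matrix.mtx")))
    features = pd.read_csv(directory / f"{prefix}_features.tsv", sep="\t",
                           header=None)[0].tolist()
    cells = pd.read_csv(directory / f"{prefix}_barcodes.tsv", sep="\t", index_col=0)
    if X.shape != (len(features), len(cells)):
        raise ValueError(
            f"{prefix}: matrix shape {X.shape} inconsistent with "
            f"{len(features)} features × {len(cells)} barcodes"
        )
    return CellMatrix(X, features, cells)


def write_bed(path: Path, peaks: pd.DataFrame) -> None:
    """BED6+3: name, score = round(10 × −log10 p), strand '.', summit offset,
    origin, category."""
    df = pd.DataFrame(
        {
            "chrom": peaks["chrom"],
            "start": peaks["start"].astype(int),
            "end": peaks["end"].astype(int),
            "peak_id": peaks["peak_id"],
            "score_i": (peaks["score"] * 10).round().astype(int),
            "strand": ".",
            "summit_offset": (peaks["summit"] - peaks["start"]).astype(int),
            "origin": peaks["origin"],
            "category": peaks.get("category", pd.Series(["."] * len(peaks))).fillna("."),
        }
    )
    df.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS)
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise ValueError(f"{path}: start >= end at line {int(bad[0]) + 1}")
    out = pd.DataFrame(
        {
            "peak_id": df["peak_id"],
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "summit": df["start"] + df["summit_offset"],
            "score": df["score_i"] / 10.0,
            "origin": df["origin"],
        }
    )
    if (df["category"] != ".").any():
        out["category"] = df["category"]
    return out


def write_fragments(path: Path, fragments: pd.DataFrame) -> None:
    fragments[["chrom", "start", "end", "barcode", "count"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_fragments(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "barcode", "count"])
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise ValueError(f"{path}: start >= end at line {int(bad[0]) + 1}")
    return df


def write_pfms(path: Path, pwms: list[PWM], counts_scale: int = 100) -> None:
    """JASPAR-style PFM files (4 rows × L integer counts) plus a metadata TSV."""
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.name} {p.annotation or p.name}\n")
            counts = np.rint(p.matrix * counts_scale).astype(int)
            for b, row in zip("ACGT", counts):
                fh.write(f"{b} [ " + " ".join(str(v) for v in row) + " ]\n")
    meta = pd.DataFrame(
        {
            "name": [p.name for p in pwms],
            "discovery_p": [p.discovery_p for p in pwms],
            "context": [json.dumps(p.context) for p in pwms],
            "annotation": [p.annotation or "" for p in pwms],
        }
    )
    meta.to_csv(path.with_suffix(".meta.tsv"), sep="\t", index=False)


def read_pfms(path: Path) -> list[PWM]:
    """Read JASPAR PFM counts and column-normalize to probabilities."""
    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    meta_path = path.with_suffix(".meta.tsv")
    meta = (
        pd.read_csv(meta_path, sep="\t").set_index("name")
        if meta_path.exists()
        else pd.DataFrame()
    )
    out = []
    for rec in records:
        mat = np.array([rec.counts[b] for b in "ACGT"], dtype=float)
        mat = mat / mat.sum(axis=0)
        name = rec.matrix_id or rec.name
        kwargs = {}
        if name in meta.index:
            kwargs["discovery_p"] = float(meta.loc[name, "discovery_p"])
            kwargs["context"] = json.loads(meta.loc[name, "context"])
            ann = meta.loc[name, "annotation"]
            kwargs["annotation"] = None if (pd.isna(ann) or ann == "") else str(ann)
        out.append(PWM(name=name, matrix=mat, **kwargs))
    return out


def write_bedgraph(path: Path, track: pd.DataFrame) -> None:
    track[["chrom", "start", "end", "score"]].to_csv(
        path, sep="\t", index=False, header=False, float_format="%.4f"
    )


def read_bedgraph(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "browser", "#")) or not line.strip():
                continue
            rows.append(line)
    df = pd.read_csv(StringIO("".join(rows)), sep="\t", header=None,
                     names=["chrom", "start", "end", "score"])
    return df


def write_truth(path: Path, truth: GroundTruth) -> None:
    payload = {
        "module_genes": [sorted(truth.module_genes[0]), sorted(truth.module_genes[1])],
        "lineage_tfs": {k: sorted(v) for k, v in truth.lineage_tfs.items()},
        "lineage_daps": {k: sorted(v) for k, v in truth.lineage_daps.items()},
        "planted_links": sorted(list(map(list, truth.planted_links))),
        "true_pseudotime": truth.true_pseudotime.to_dict(),
        "cell_labels": truth.cell_labels.to_dict(orient="index"),
        "motif_truth": {k: sorted(v) for k, v in truth.motif_truth.items()},
        "cre_sharing": truth.cre_sharing,
        "paired_cells": truth.paired_cells,
    }
    path.write_text(json.dumps(payload))


def read_truth(path: Path) -> GroundTruth:
    d = json.loads(path.read_text())
    labels = pd.DataFrame.from_dict(d["cell_labels"], orient="index")
    return GroundTruth(
        module_genes=(set(d["module_genes"][0]), set(d["module_genes"][1])),
        lineage_tfs={k: set(v) for k, v in d["lineage_tfs"].items()},
        lineage_daps={k: set(v) for k, v in d["lineage_daps"].items()},
        planted_links={tuple(x) for x in d["planted_links"]},
        true_pseudotime=pd.Series(d["true_pseudotime"]),
        cell_labels=labels,
        motif_truth={k: set(v) for k, v in d["motif_truth"].items()},
        cre_sharing=d["cre_sharing"],
        paired_cells=d["paired_cells"],
    )


def write_fixtures(cohort: SyntheticCohort, directory: str | Path,
                   include_fragments: bool = True) -> Path:
    """Write a cohort as a standard-format file bundle."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_matrix(d, "rna", cohort.rna)
    write_matrix(d, "atac", cohort.atac)
    write_bed(d / "peaks.bed", cohort.peaks)
    cohort.peaks.to_csv(d / "peaks_attrs.tsv", sep="\t", index=False)
    cohort.genes.to_csv(d / "genes.tsv", sep="\t", index=False)
    pd.Series(cohort.genome_sizes).to_csv(d / "chrom_sizes.tsv", sep="\t", header=False)
    if include_fragments:
        write_fragments(d / "fragments.tsv", cohort.fragments)
    write_pfms(d / "denovo_pfms.jaspar", cohort.pwms["denovo"])
    write_pfms(d / "reference_pfms.jaspar", cohort.pwms["reference"])
    write_pfms(d / "context_pfms.jaspar", cohort.pwms["context"])
    pd.Series(cohort.pwms["tf_of_reference"]).to_csv(
        d / "tf_of_reference.tsv", sep="\t", header=False
    )
    write_bedgraph(d / "conservation.bedGraph", cohort.conservation)
    write_truth(d / "truth.json", cohort.truth)
    (d / "config.json").write_text(json.dumps(cohort.config.__dict__))
    return d


def read_bundle(directory: str | Path) -> SyntheticCohort:
    """Read a fixture bundle back into a cohort object.

    Coordinates are validated (0-based half-open, start < end) and matrix
    dimensions are checked against their annotation tables.
    """
    d = Path(directory)
    cfg_raw = json.loads((d / "config.json").read_text())
    for key in ("n_module_genes", "depth_lognormal_params", "motif_lengths",
                "conservation_levels"):
        cfg_raw[key] = tuple(cfg_raw[key])
    cfg = SimConfig(**cfg_raw)
    rna = read_matrix(d, "rna")
    atac = read_matrix(d, "atac")
    peaks = pd.read_csv(d / "peaks_attrs.tsv", sep="\t")
    genes = pd.read_csv(d / "genes.tsv", sep="\t")
    sizes = pd.read_csv(d / "chrom_sizes.tsv", sep="\t", header=None,
                        index_col=0)[1].to_dict()
    frag_path = d / "fragments.tsv"
    fragments = read_fragments(frag_path) if frag_path.exists() else None
    pwms = {
        "denovo": read_pfms(d / "denovo_pfms.jaspar"),
        "reference": read_pfms(d / "reference_pfms.jaspar"),
        "context": read_pfms(d / "context_pfms.jaspar"),
        "tf_of_reference": pd.read_csv(d / "tf_of_reference.tsv", sep="\t",
                                       header=None, index_col=0)[1].to_dict(),
    }
    conservation = read_bedgraph(d / "conservation.bedGraph")
    truth = read_truth(d / "truth.json")
    for chrom, grp in peaks.groupby("chrom"):
        if chrom not in sizes:
            raise ValueError(f"peaks reference unknown chromosome {chrom}")
        if (grp["end"] > sizes[chrom]).any():
            raise ValueError(f"peak beyond {chrom} bounds")
    return SyntheticCohort(
        config=cfg, rna=rna, atac=atac, genome_sizes=sizes, genes=genes,
        peaks=peaks, pwms=pwms, conservation=conservation, truth=truth,
        _fragments=fragments,
    )
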