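"""Three-lineage synthetic multi-omic cohorts with planted ground truth.

The generator emulates the structure of a cross-lineage chondrogenic
convergence study: three embryonic lineages (NC, SOM, LPM — neural crest,
somitic mesoderm, lateral plate mesoderm) each carry cells along a
continuous pseudotime t ∈ [0, 1].  A shared chondrogenic gene module (two
sub-modules, 17 + 41 genes by default) rises along t in every lineage;
lineage-specific transcription-factor programs peak *before* the module's
rise and are expressed only in their own lineage; promoter-proximal peaks of
module genes open with t in all lineages while lineage-specific distal peaks
(DAPs) open only in theirs; planted peak→gene links tie CRE accessibility to
target-gene expression through per-cell latent factors; de-novo-like PWMs
with known source TFs hit their lineage's DAPs; and per-base conservation is
elevated on shared elements.

RNA counts are negative binomial (mean/dispersion with a lognormal per-cell
depth multiplier); ATAC counts are Poisson.  Everything is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .motifs import PWM

LINEAGES = ["NC", "SOM", "LPM"]
GENE_SPACING = 600_000
GENE_LENGTH = 5_000
PEAK_WIDTH = 501
MODULE_SIGMOID_SCALE = 0.08
TF_BUMP_SCALE = 0.12
TF_LINEAGE_OFFSET = 1.2
ATAC_OPEN_EFFECT = 1.2
LINK_AMPLITUDE = 1.2
ATAC_LINK_AMPLITUDE = 1.0
ATAC_TARGET_DEPTH = 2200.0
# embryonic stage tracks pseudotime only loosely: every stage sample contains
# cells across the whole differentiation spectrum
STAGE_TIME_WEIGHT = 0.3
N_MITO_GENES = 5
N_DECOY_REFERENCE = 6
N_CONTEXT_MES_TFS = 5
N_CONTEXT_NONMES_TFS = 3


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort."""

    seed: int = 0
    n_lineages: int = 3
    cells_per_lineage: int = 1500
    n_genes: int = 400
    n_module_genes: tuple[int, int] = (17, 41)
    n_tf_per_lineage: int = 8
    n_peaks: int = 600
    frac_promoter: float = 0.4
    n_lineage_daps: int = 80
    n_planted_links: int = 30
    nb_dispersion: float = 5.0
    depth_lognormal_params: tuple[float, float] = (0.0, 0.35)
    tf_bump_center: float = 0.35
    chondro_midpoint: float = 0.65
    effect_size_logfc: float = 1.5
    motif_lengths: tuple[int, int] = (8, 22)
    conservation_levels: tuple[float, float, float] = (0.8, 0.35, 0.1)

    def __post_init__(self):
        if not (0 < self.n_lineages <= len(LINEAGES)):
            raise ValueError("n_lineages must be 1..3")
        if self.tf_bump_center >= self.chondro_midpoint:
            raise ValueError("tf_bump_center must precede chondro_midpoint")
        if not (0 < self.frac_promoter < 1):
            raise ValueError("frac_promoter must lie in (0, 1)")
        for name in ("cells_per_lineage", "n_genes", "n_tf_per_lineage",
                     "n_peaks", "n_lineage_daps", "n_planted_links"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        m1, m2 = self.n_module_genes
        needed = 2 * (m1 + m2) + self.n_lineages * self.n_tf_per_lineage \
            + self.n_planted_links + N_MITO_GENES + 10
        if self.n_genes < needed:
            raise ValueError(f"n_genes must be at least {needed} for this configuration")

    @property
    def lineages(self) -> list[str]:
        return LINEAGES[: self.n_lineages]


@dataclass
class CellMatrix:
    """Sparse features × cells counts with per-cell metadata."""

    X: sparse.csr_matrix
    feature_ids: list[str]
    cells: pd.DataFrame  # index: cell ids; columns incl. lineage/stage/cluster/pseudotime

    def to_anndata(self):
        """Cells × features AnnData view (the field's standard container)."""
        import anndata as ad

        return ad.AnnData(
            X=self.X.T.tocsr(),
            obs=self.cells.copy(),
            var=pd.DataFrame(index=self.feature_ids),
        )


@dataclass
class GroundTruth:
    module_genes: tuple[set[str], set[str]]
    lineage_tfs: dict[str, set[str]]
    lineage_daps: dict[str, set[str]]
    planted_links: set[tuple[str, str]]
    true_pseudotime: pd.Series
    cell_labels: pd.DataFrame
    motif_truth: dict[str, set[str]]
    cre_sharing: dict[str, str]        # peak id -> 'common' / 'specific_<lineage>'
    paired_cells: dict[str, str] | None = None


@dataclass
class SyntheticCohort:
    config: SimConfig
    rna: CellMatrix
    atac: CellMatrix
    genome_sizes: dict[str, int]
    genes: pd.DataFrame
    peaks: pd.DataFrame
    pwms: dict
    conservation: pd.DataFrame
    truth: GroundTruth
    _fragments: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def fragments(self) -> pd.DataFrame:
        """Fragments table (chrom, start, end, barcode, count), built lazily."""
        if self._fragments is None:
            self._fragments = _make_fragments(self)
        return self._fragments

    @property
    def hit_matrix(self) -> pd.DataFrame:
        """Planted peak × motif occurrence matrix."""
        peak_ids = self.peaks["peak_id"].tolist()
        motifs = sorted(self.truth.motif_truth)
        H = pd.DataFrame(False, index=peak_ids, columns=motifs)
        for m, pset in self.truth.motif_truth.items():
            H.loc[list(pset), m] = True
        return H


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _build_genes(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    m1, m2 = cfg.n_module_genes
    names, kinds, lineages = [], [], []
    names += [f"IMM_{i+1:02d}" for i in range(m1)]
    kinds += ["module_imm"] * m1
    lineages += [""] * m1
    names += [f"RED_{i+1:02d}" for i in range(m2)]
    kinds += ["module_red"] * m2
    lineages += [""] * m2
    # the precursor program: one declining gene per module gene, with exactly
    # complementary dynamics so the expected transcriptome size stays flat
    names += [f"EARLY_{i+1:02d}" for i in range(m1 + m2)]
    kinds += ["early"] * (m1 + m2)
    lineages += [""] * (m1 + m2)
    names += [f"LNK_{i+1:02d}" for i in range(cfg.n_planted_links)]
    kinds += ["link_target"] * cfg.n_planted_links
    lineages += [""] * cfg.n_planted_links
    names += [f"MT-{i+1}" for i in range(N_MITO_GENES)]
    kinds += ["mito"] * N_MITO_GENES
    lineages += [""] * N_MITO_GENES
    for lin in cfg.lineages:
        names += [f"TF_{lin}_{i+1}" for i in range(cfg.n_tf_per_lineage)]
        kinds += ["tf"] * cfg.n_tf_per_lineage
        lineages += [lin] * cfg.n_tf_per_lineage
    n_fill = cfg.n_genes - len(names)
    names += [f"FILL_{i+1:04d}" for i in range(n_fill)]
    kinds += ["filler"] * n_fill
    lineages += [""] * n_fill

    df = pd.DataFrame({"gene_id": names, "kind": kinds, "tf_lineage": lineages})
    # chromosome assignment: TFs and a share of fillers on lineage chromosomes,
    # everything else on the shared chromosome
    chrom = []
    for kind, lin in zip(df["kind"], df["tf_lineage"]):
        chrom.append(f"chr{lin}" if kind == "tf" else "chrShared")
    n_lin = cfg.n_lineages
    fill_rows = df.index[df["kind"] == "filler"]
    for j, row in enumerate(fill_rows):
        if j % 3 != 0:  # two thirds of fillers spread over lineage chromosomes
            chrom[row] = f"chr{cfg.lineages[j % n_lin]}"
    df["chrom"] = chrom

    # strand-aware placement on a regular grid per chromosome
    tss, start, end, strand = [], [], [], []
    slot = {c: 0 for c in df["chrom"].unique()}
    for i, c in enumerate(df["chrom"]):
        k = slot[c]
        slot[c] += 1
        pos = (k + 1) * GENE_SPACING
        st = "+" if k % 2 == 0 else "-"
        tss.append(pos)
        strand.append(st)
        if st == "+":
            start.append(pos)
            end.append(pos + GENE_LENGTH)
        else:
            start.append(pos - GENE_LENGTH + 1)
            end.append(pos + 1)
    df["tss"], df["start"], df["end"], df["strand"] = tss, start, end, strand

    # per-gene dynamic parameters, shared across lineages; module genes
    # switch on at staggered pseudotimes (after the TF wave), which is what
    # lets chromatin state encode position along the whole trajectory
    df["sim_base"] = np.nan
    df["sim_amp"] = np.nan
    df["sim_mid"] = np.nan
    mod_rows = df.index[df["kind"].isin(["module_imm", "module_red"])]
    lo = cfg.tf_bump_center + 0.1
    hi = min(cfg.chondro_midpoint + 0.15, 0.95)
    df.loc[mod_rows, "sim_base"] = np.exp(rng.normal(np.log(0.8), 0.6, len(mod_rows)))
    df.loc[mod_rows, "sim_amp"] = rng.uniform(0.7, 1.3, len(mod_rows))
    df.loc[mod_rows, "sim_mid"] = rng.uniform(min(lo, hi - 0.05), hi, len(mod_rows))
    early_rows = df.index[df["kind"] == "early"]
    for col in ("sim_base", "sim_amp", "sim_mid"):
        df.loc[early_rows, col] = df.loc[mod_rows, col].to_numpy()[: len(early_rows)]
    return df


def _build_peaks(cfg: SimConfig, genes: pd.DataFrame, rng: np.random.Generator):
    """Peak table plus per-peak simulation attributes and sharing labels."""
    half = (PEAK_WIDTH - 1) // 2
    rows = []
    cre_sharing: dict[str, str] = {}
    planted_links: set[tuple[str, str]] = set()

    n_prom = int(round(cfg.frac_promoter * cfg.n_peaks))
    promoter_priority = genes[genes["kind"].isin(
        ["module_imm", "module_red", "early", "link_target", "tf", "mito", "filler"])]
    promoter_genes = promoter_priority.iloc[:n_prom]
    for _, g in promoter_genes.iterrows():
        summit = g["tss"] - 200 if g["strand"] == "+" else g["tss"] + 200
        pid = f"peak_prom_{g['gene_id']}"
        if g["kind"].startswith("module"):
            cls = "promoter_module"
        elif g["kind"] == "early":
            cls = "promoter_early"
        else:
            cls = "promoter_flat"
        rows.append({
            "peak_id": pid, "chrom": g["chrom"], "start": summit - half,
            "end": summit + half + 1, "summit": summit,
            "score": float(rng.uniform(5, 60)), "origin": "shared",
            "sim_class": cls, "sim_gene": g["gene_id"], "sim_lineage": "",
            "sim_mid": float(g["sim_mid"]) if np.isfinite(g["sim_mid"]) else np.nan,
        })
        if cls != "promoter_flat":
            planted_links.add((pid, g["gene_id"]))
            cre_sharing[pid] = "common"

    # planted distal CREs near link-target genes: first third shared across
    # lineages, the rest one lineage-specific CRE per lineage
    link_genes = genes[genes["kind"] == "link_target"]
    n_common = max(1, len(link_genes) // 3)
    for gi, (_, g) in enumerate(link_genes.iterrows()):
        if gi < n_common:
            summit = g["tss"] + 40_000
            pid = f"peak_cre_{g['gene_id']}_common"
            rows.append({
                "peak_id": pid, "chrom": g["chrom"], "start": summit - half,
                "end": summit + half + 1, "summit": summit,
                "score": float(rng.uniform(5, 60)), "origin": "shared",
                "sim_class": "cre_common", "sim_gene": g["gene_id"], "sim_lineage": "",
            })
            planted_links.add((pid, g["gene_id"]))
            cre_sharing[pid] = "common"
        else:
            for li, lin in enumerate(cfg.lineages):
                summit = g["tss"] + 40_000 + 25_000 * li
                pid = f"peak_cre_{g['gene_id']}_{lin}"
                rows.append({
                    "peak_id": pid, "chrom": g["chrom"], "start": summit - half,
                    "end": summit + half + 1, "summit": summit,
                    "score": float(rng.uniform(5, 60)), "origin": lin,
                    "sim_class": "cre_lineage", "sim_gene": g["gene_id"],
                    "sim_lineage": lin,
                })
                planted_links.add((pid, g["gene_id"]))
                cre_sharing[pid] = f"specific_{lin}"

    # lineage-specific DAP blocks in gene deserts of the lineage chromosomes
    lineage_daps: dict[str, set[str]] = {lin: set() for lin in cfg.lineages}
    for lin in cfg.lineages:
        chrom = f"chr{lin}"
        n_gene_slots = int((genes["chrom"] == chrom).sum())
        base = (n_gene_slots + 2) * GENE_SPACING
        for d in range(cfg.n_lineage_daps):
            summit = base + d * 3_000
            pid = f"peak_dap_{lin}_{d+1:03d}"
            rows.append({
                "peak_id": pid, "chrom": chrom, "start": summit - half,
                "end": summit + half + 1, "summit": summit,
                "score": float(rng.uniform(5, 60)), "origin": lin,
                "sim_class": "dap", "sim_gene": "", "sim_lineage": lin,
                "sim_mid": float(rng.uniform(0.25, 0.85)),
            })
            lineage_daps[lin].add(pid)
            cre_sharing[pid] = f"specific_{lin}"

    n_bg = cfg.n_peaks - len(rows)
    if n_bg < 0:
        raise ValueError("n_peaks too small for the requested promoter/DAP/link structure")
    n_shared_slots = int((genes["chrom"] == "chrShared").sum())
    base = (n_shared_slots + 2) * GENE_SPACING
    for b in range(n_bg):
        summit = base + b * 3_000
        pid = f"peak_bg_{b+1:04d}"
        rows.append({
            "peak_id": pid, "chrom": "chrShared", "start": summit - half,
            "end": summit + half + 1, "summit": summit,
            "score": float(rng.uniform(5, 60)), "origin": "shared",
            "sim_class": "background", "sim_gene": "", "sim_lineage": "",
        })
    peaks = pd.DataFrame(rows)
    peaks["gc"] = rng.uniform(0.35, 0.65, size=len(peaks))
    # per-peak baseline accessibility, shared across lineages: cross-lineage
    # agreement of constitutive peaks is carried by this factor, while
    # lineage-gated opening dominates it on planted DAPs
    peaks["base_factor"] = rng.lognormal(0.0, 0.4, size=len(peaks))
    return peaks, lineage_daps, planted_links, cre_sharing


def _genome_sizes(cfg: SimConfig, genes: pd.DataFrame, peaks: pd.DataFrame) -> dict[str, int]:
    sizes = {}
    for chrom in sorted(set(genes["chrom"]) | set(peaks["chrom"])):
        hi = max(genes.loc[genes["chrom"] == chrom, "end"].max() if (genes["chrom"] == chrom).any() else 0,
                 peaks.loc[peaks["chrom"] == chrom, "end"].max() if (peaks["chrom"] == chrom).any() else 0)
        sizes[chrom] = int(hi + GENE_SPACING)
    return sizes


def _make_pwm_core(rng: np.random.Generator, length: int) -> np.ndarray:
    cols = []
    for _ in range(length):
        dom = rng.integers(0, 4)
        p = np.full(4, 0.05)
        p[dom] = 0.85
        p = p + rng.uniform(0, 0.02, 4)
        cols.append(p / p.sum())
    return np.column_stack(cols)


def _uniform_flanks(rng: np.random.Generator, core: np.ndarray, max_flank: int = 3) -> np.ndarray:
    def flank(n):
        # near-uniform columns: IC well below any trimming threshold
        return np.column_stack([
            np.full(4, 0.25) + rng.uniform(-0.01, 0.01, 4) for _ in range(n)
        ])

    left = flank(int(rng.integers(1, max_flank + 1)))
    right = flank(int(rng.integers(1, max_flank + 1)))
    m = np.hstack([left, core, right])
    return m / m.sum(axis=0)


def _noisy(rng: np.random.Generator, core: np.ndarray, scale: float = 0.05) -> np.ndarray:
    m = core + rng.uniform(0, scale, core.shape)
    return m / m.sum(axis=0)


def _build_pwms(cfg: SimConfig, rng: np.random.Generator, genes: pd.DataFrame):
    lo, hi = cfg.motif_lengths
    reference: list[PWM] = []
    tf_of_reference: dict[str, str] = {}
    tf_cores: dict[str, np.ndarray] = {}
    tf_genes = genes.loc[genes["kind"] == "tf"]
    for _, g in tf_genes.iterrows():
        core = _make_pwm_core(rng, int(rng.integers(max(lo, 8), min(hi, 14) + 1)))
        tf_cores[g["gene_id"]] = core
        name = f"REF_{g['gene_id']}"
        reference.append(PWM(name=name, matrix=core, discovery_p=1e-10,
                             context={"source": "reference"}))
        tf_of_reference[name] = g["gene_id"]
    for d in range(N_DECOY_REFERENCE):
        core = _make_pwm_core(rng, int(rng.integers(8, 13)))
        name = f"REF_DECOY_{d+1}"
        reference.append(PWM(name=name, matrix=core, discovery_p=1e-10,
                             context={"source": "reference"}))

    denovo: list[PWM] = []
    for _, g in tf_genes.iterrows():
        lin = g["tf_lineage"]
        mat = _uniform_flanks(rng, _noisy(rng, tf_cores[g["gene_id"]]))
        denovo.append(PWM(
            name=f"DN_{g['gene_id']}",
            matrix=mat,
            discovery_p=float(10.0 ** -rng.uniform(12, 30)),
            context={"cluster": "EC", "lineage": lin, "mesenchymal": True,
                     "source_tf": g["gene_id"]},
        ))

    # context-comparison motifs: the same TF recovered in each lineage, with
    # lineage-specific heterodimeric 5' extensions in mesenchymal contexts and
    # exact copies in non-mesenchymal contexts
    context: list[PWM] = []
    for m in range(N_CONTEXT_MES_TFS):
        core = _make_pwm_core(rng, 9)
        for lin in cfg.lineages:
            ext = _make_pwm_core(rng, int(rng.integers(3, 6)))
            mat = _uniform_flanks(rng, np.hstack([ext, _noisy(rng, core, 0.03)]))
            context.append(PWM(
                name=f"CTX_MES{m+1}_{lin}", matrix=mat,
                discovery_p=float(10.0 ** -rng.uniform(12, 30)),
                context={"cluster": "mesenchyme", "lineage": lin, "mesenchymal": True,
                         "source_tf": f"CTXTF_MES{m+1}"},
            ))
    for m in range(N_CONTEXT_NONMES_TFS):
        core = _make_pwm_core(rng, 10)
        for lin in cfg.lineages:
            mat = _uniform_flanks(rng, core)
            context.append(PWM(
                name=f"CTX_NON{m+1}_{lin}", matrix=mat,
                discovery_p=float(10.0 ** -rng.uniform(12, 30)),
                context={"cluster": "skin", "lineage": lin, "mesenchymal": False,
                         "source_tf": f"CTXTF_NON{m+1}"},
            ))
    return {"denovo": denovo, "reference": reference, "context": context,
            "tf_of_reference": tf_of_reference}


def _plant_motif_hits(cfg: SimConfig, rng: np.random.Generator,
                      peaks: pd.DataFrame, denovo: list[PWM],
                      lineage_daps: dict[str, set[str]]) -> dict[str, set[str]]:
    peak_ids = peaks["peak_id"].to_numpy()
    truth: dict[str, set[str]] = {}
    for pwm in denovo:
        lin = pwm.context["lineage"]
        own = np.array(sorted(lineage_daps[lin]))
        take = own[rng.random(len(own)) < 0.65]
        bg = peak_ids[rng.random(len(peak_ids)) < 0.04]
        truth[pwm.name] = set(take) | set(bg)
    return truth


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw one synthetic three-lineage multi-omic cohort."""
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    (r_layout, r_cells, r_rna, r_atac, r_pwm, r_cons) = [
        np.random.default_rng(s) for s in ss.spawn(6)
    ]

    genes = _build_genes(cfg, r_layout)
    peaks, lineage_daps, planted_links, cre_sharing = _build_peaks(cfg, genes, r_layout)
    sizes = _genome_sizes(cfg, genes, peaks)
    pwms = _build_pwms(cfg, r_pwm, genes)
    motif_truth = _plant_motif_hits(cfg, r_pwm, peaks, pwms["denovo"], lineage_daps)

    # ---- cells -----------------------------------------------------------
    n_cells = cfg.n_lineages * cfg.cells_per_lineage
    lineage = np.repeat(cfg.lineages, cfg.cells_per_lineage)
    t = r_cells.uniform(0, 1, n_cells)
    stage_t = np.clip(
        STAGE_TIME_WEIGHT * t + (1 - STAGE_TIME_WEIGHT) * r_cells.uniform(0, 1, n_cells),
        0, 1,
    )
    stage = np.array(["S1", "S2", "S3"])[np.minimum((stage_t * 3).astype(int), 2)]
    cluster = np.array(["PC", "other", "EC"])[np.minimum((t * 3).astype(int), 2)]
    cell_ids = [f"{lin}_{i+1:05d}" for lin, i in zip(lineage, range(n_cells))]
    mu_d, sd_d = cfg.depth_lognormal_params
    depth = r_cells.lognormal(mu_d, sd_d, n_cells)
    adepth = r_cells.lognormal(0.0, 0.3, n_cells)

    # per-link latent factors
    link_genes = genes.loc[genes["kind"] == "link_target", "gene_id"].tolist()
    latents = {}
    lin_index = {lin: i for i, lin in enumerate(cfg.lineages)}
    for g in link_genes:
        latents[g] = np.clip(r_cells.normal(0, 1, (cfg.n_lineages, n_cells)), -2.5, 2.5)

    # ---- RNA counts ------------------------------------------------------
    module_ramp = cfg.effect_size_logfc * _sigmoid((t - cfg.chondro_midpoint) / MODULE_SIGMOID_SCALE)
    tf_bump = cfg.effect_size_logfc * np.exp(-((t - cfg.tf_bump_center) ** 2) / (2 * TF_BUMP_SCALE**2))

    log_mu = np.empty((cfg.n_genes, n_cells))
    lin_codes = np.array([lin_index[l] for l in lineage])
    for i, g in genes.iterrows():
        kind = g["kind"]
        if kind in ("module_imm", "module_red"):
            # per-gene baseline/amplitude/switch-point are shared across
            # lineages: the module converges with gene-specific magnitudes,
            # which is what makes cross-lineage profiles rankable
            a_eff = cfg.effect_size_logfc * g["sim_amp"]
            ramp = a_eff * _sigmoid((t - g["sim_mid"]) / MODULE_SIGMOID_SCALE)
            log_mu[i] = np.log(g["sim_base"]) + ramp
        elif kind == "early":
            # mirror of one module gene: mean_early + mean_module is constant
            # in t, so depth normalization carries no pseudotime signal
            a_eff = cfg.effect_size_logfc * g["sim_amp"]
            s = _sigmoid((t - g["sim_mid"]) / MODULE_SIGMOID_SCALE)
            log_mu[i] = np.log(g["sim_base"] * (1.0 + np.exp(a_eff) - np.exp(a_eff * s)))
        elif kind == "tf":
            own = lineage == g["tf_lineage"]
            log_mu[i] = np.log(0.1) + own * (TF_LINEAGE_OFFSET + tf_bump)
        elif kind == "link_target":
            u = latents[g["gene_id"]][lin_codes, np.arange(n_cells)]
            log_mu[i] = np.log(2.0) + LINK_AMPLITUDE * (cfg.effect_size_logfc / 1.5) * u
        elif kind == "mito":
            log_mu[i] = np.log(1.0)
        else:
            base = float(np.exp(r_rna.normal(np.log(0.4), 0.5)))
            log_mu[i] = np.log(base)
    mu = np.exp(log_mu) * depth[None, :]
    r = cfg.nb_dispersion
    rna_counts = r_rna.negative_binomial(r, r / (r + mu))
    rna_X = sparse.csr_matrix(rna_counts)

    cells = pd.DataFrame(
        {"lineage": lineage, "stage": stage, "cluster": cluster,
         "pseudotime": t, "depth_factor": depth},
        index=cell_ids,
    )

    # ---- ATAC counts -----------------------------------------------------
    atac_cells = pd.DataFrame(
        {"lineage": lineage, "stage": stage, "cluster": cluster,
         "pseudotime": t, "depth_factor": adepth},
        index=[f"atac_{c}" for c in cell_ids],
    )
    # chromatin opening scales with the configured effect size
    a_open = ATAC_OPEN_EFFECT * cfg.effect_size_logfc / 1.5
    lam = np.empty((len(peaks), n_cells))
    for i, p in peaks.iterrows():
        cls = p["sim_class"]
        if cls == "promoter_module":
            s = _sigmoid((t - p["sim_mid"]) / MODULE_SIGMOID_SCALE)
            lam[i] = 4.0 * np.exp(a_open * s)
        elif cls == "promoter_early":
            s = _sigmoid((t - p["sim_mid"]) / MODULE_SIGMOID_SCALE)
            lam[i] = 4.0 * (1.0 + np.exp(a_open) - np.exp(a_open * s))
        elif cls == "promoter_flat":
            lam[i] = 4.0
        elif cls == "dap":
            own = lineage == p["sim_lineage"]
            s = _sigmoid((t - p["sim_mid"]) / MODULE_SIGMOID_SCALE)
            lam[i] = 1.0 * np.exp(own * a_open * s)
        elif cls == "cre_common":
            u = latents[p["sim_gene"]][lin_codes, np.arange(n_cells)]
            lam[i] = 3.0 * np.exp(ATAC_LINK_AMPLITUDE * (cfg.effect_size_logfc / 1.5) * u)
        elif cls == "cre_lineage":
            li = lin_index[p["sim_lineage"]]
            own = lineage == p["sim_lineage"]
            u = latents[p["sim_gene"]][li]
            lam[i] = 3.0 * np.exp(ATAC_LINK_AMPLITUDE * (cfg.effect_size_logfc / 1.5) * u * own)
        else:
            lam[i] = 3.0
        lam[i] *= p["base_factor"]
    lam *= adepth[None, :]
    lam *= ATAC_TARGET_DEPTH / lam.sum(axis=0).mean()
    atac_counts = r_atac.poisson(lam)
    atac_X = sparse.csr_matrix(atac_counts)

    # ---- conservation ----------------------------------------------------
    shared_mean, specific_mean, noise_sd = cfg.conservation_levels
    cons_rows = []
    for _, p in peaks.iterrows():
        pid = p["peak_id"]
        sharing = cre_sharing.get(pid)
        if sharing == "common" or p["sim_class"].startswith("promoter"):
            m = shared_mean
        elif sharing is not None:
            m = specific_mean
        else:
            m = specific_mean
        var = max(noise_sd, 1e-3) ** 2
        var = min(var, m * (1 - m) * 0.95)
        conc = m * (1 - m) / var - 1
        a, b = m * conc, (1 - m) * conc
        scores = r_cons.beta(a, b, p["end"] - p["start"])
        cons_rows.append(pd.DataFrame({
            "chrom": p["chrom"],
            "start": np.arange(p["start"], p["end"]),
            "end": np.arange(p["start"], p["end"]) + 1,
            "score": scores,
        }))
    conservation = pd.concat(cons_rows, ignore_index=True)

    m1, m2 = cfg.n_module_genes
    truth = GroundTruth(
        module_genes=(
            set(genes.loc[genes["kind"] == "module_imm", "gene_id"]),
            set(genes.loc[genes["kind"] == "module_red", "gene_id"]),
        ),
        lineage_tfs={
            lin: set(genes.loc[(genes["kind"] == "tf") & (genes["tf_lineage"] == lin), "gene_id"])
            for lin in cfg.lineages
        },
        lineage_daps=lineage_daps,
        planted_links=planted_links,
        true_pseudotime=pd.Series(t, index=cell_ids),
        cell_labels=cells[["lineage", "stage", "cluster"]].copy(),
        motif_truth=motif_truth,
        cre_sharing=cre_sharing,
        paired_cells={a: c for a, c in zip(atac_cells.index, cell_ids)},
    )
    return SyntheticCohort(
        config=cfg,
        rna=CellMatrix(rna_X, genes["gene_id"].tolist(), cells),
        atac=CellMatrix(atac_X, peaks["peak_id"].tolist(), atac_cells),
        genome_sizes=sizes,
        genes=genes,
        peaks=peaks,
        pwms=pwms,
        conservation=conservation,
        truth=truth,
    )


def _make_fragments(cohort: SyntheticCohort) -> pd.DataFrame:
    """Expand ATAC counts into a fragments table with a bimodal length mix.

    Each in-peak count becomes one fragment centered inside its peak; an
    extra ~30% background fragments per cell land uniformly on the genome.
    Lengths mix nucleosome-free (~50–140 bp) and mono-nucleosome
    (~160–280 bp) modes.
    """
    cfg = cohort.config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(7)[6])
    X = cohort.atac.X.tocoo()
    peak_start = cohort.peaks["start"].to_numpy()
    peak_end = cohort.peaks["end"].to_numpy()
    peak_chrom = cohort.peaks["chrom"].to_numpy()
    barcodes = np.array(cohort.atac.cells.index)

    reps = X.data.astype(int)
    p_idx = np.repeat(X.row, reps)
    c_idx = np.repeat(X.col, reps)
    n_in = p_idx.size

    def draw_lengths(n):
        is_nfr = rng.random(n) < 0.55
        lens = np.where(
            is_nfr,
            np.clip(rng.normal(90, 20, n), 50, 140),
            np.clip(rng.normal(210, 28, n), 160, 280),
        )
        return lens.astype(int)

    lens = draw_lengths(n_in)
    span = peak_end[p_idx] - peak_start[p_idx]
    mid = peak_start[p_idx] + (rng.random(n_in) * span).astype(int)
    start = np.maximum(mid - lens // 2, 0)
    end = start + lens
    chrom = peak_chrom[p_idx]
    bc = barcodes[c_idx]

    # background fragments outside the planted signal
    totals = np.asarray(cohort.atac.X.sum(axis=0)).ravel().astype(int)
    n_bg_per_cell = rng.poisson(0.3 * totals)
    n_bg = int(n_bg_per_cell.sum())
    bg_cell = np.repeat(np.arange(len(totals)), n_bg_per_cell)
    chroms = list(cohort.genome_sizes)
    sizes = np.array([cohort.genome_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    bg_chrom_idx = rng.choice(len(chroms), size=n_bg, p=probs)
    bg_lens = draw_lengths(n_bg)
    bg_start = (rng.random(n_bg) * (sizes[bg_chrom_idx] - 300)).astype(int)
    frag = pd.DataFrame(
        {
            "chrom": np.concatenate([chrom, np.array(chroms, dtype=object)[bg_chrom_idx]]),
            "start": np.concatenate([start, bg_start]),
            "end": np.concatenate([end, bg_start + bg_lens]),
            "barcode": np.concatenate([bc, barcodes[bg_cell]]),
            "count": 1,
        }
    )
    return frag.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def null_cohort(cohort: SyntheticCohort, seed: int | None = None) -> SyntheticCohort:
    """Remove all planted label structure while keeping marginals.

    Cell labels (pseudotime, stage, cluster) are shuffled among cells within
    lineage × depth-quartile strata, so group membership is independent of
    every feature while the depth composition of each stratum is preserved.
    The matched ATAC cells receive the same permutation; the returned truth
    records no planted effects.
    """
    cfg = cohort.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    cells = cohort.rna.cells.copy()
    perm = np.arange(len(cells))
    depth = cells["depth_factor"].to_numpy()
    for lin in cfg.lineages:
        idx = np.flatnonzero(cells["lineage"].to_numpy() == lin)
        q = pd.qcut(depth[idx], 4, labels=False)
        for stratum in range(4):
            members = idx[q == stratum]
            perm[members] = rng.permutation(members)
    label_cols = ["pseudotime", "stage", "cluster"]
    cells[label_cols] = cells[label_cols].to_numpy()[perm]
    atac_cells = cohort.atac.cells.copy()
    atac_cells[label_cols] = atac_cells[label_cols].to_numpy()[perm]

    truth = GroundTruth(
        module_genes=(set(), set()),
        lineage_tfs={lin: set() for lin in cfg.lineages},
        lineage_daps={lin: set() for lin in cfg.lineages},
        planted_links=set(),
        true_pseudotime=pd.Series(cells["pseudotime"].to_numpy(), index=cells.index),
        cell_labels=cells[["lineage", "stage", "cluster"]].copy(),
        motif_truth={},
        cre_sharing={},
        paired_cells=cohort.truth.paired_cells,
    )
    return SyntheticCohort(
        config=cfg,
        rna=CellMatrix(cohort.rna.X, list(cohort.rna.feature_ids), cells),
        atac=CellMatrix(cohort.atac.X, list(cohort.atac.feature_ids), atac_cells),
        genome_sizes=dict(cohort.genome_sizes),
        genes=cohort.genes,
        peaks=cohort.peaks,
        pwms=cohort.pwms,
        conservation=cohort.conservation,
        truth=truth,
    )
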