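"""Position weight matrix handling and motif-activity scoring.

Covers the trans-regulatory arm of the analysis: trimming uninformative PWM
flanks, scoring motif similarity (ungapped alignment over both strands),
collapsing redundant motifs, scanning toy sequences, chromVAR-style per-cell
deviation z-scores with GC/accessibility-matched background peak sets, and
annotating de-novo motifs with candidate transcription factors by combining
motif similarity with activity–expression correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components
from sklearn.neighbors import NearestNeighbors

ALPHABET = "ACGT"
_COMP = np.array([3, 2, 1, 0])  # A<->T, C<->G row permutation


@dataclass
class PWM:
    """A 4×L column-stochastic probability matrix (rows A, C, G, T)."""

    name: str
    matrix: np.ndarray
    discovery_p: float = 1.0
    context: dict = field(default_factory=dict)
    annotation: str | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError(f"{self.name}: PWM must have 4 rows")
        if self.matrix.shape[1] < 4:
            raise ValueError(f"{self.name}: PWM must have length >= 4")
        if np.any(self.matrix < 0):
            raise ValueError(f"{self.name}: negative probabilities")
        colsums = self.matrix.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError(f"{self.name}: columns must sum to 1")
        self.matrix = self.matrix / colsums

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def reverse_complement(self) -> "PWM":
        return replace(self, matrix=self.matrix[_COMP][:, ::-1])

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=0))


def ic_profile(pwm: PWM) -> np.ndarray:
    """Per-column information content in bits against a uniform background."""
    p = pwm.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(p > 0, p * np.log2(p), 0.0)
    return 2.0 + term.sum(axis=0)


def trim_pwm(pwm: PWM, min_ic: float = 0.25) -> PWM:
    """Strip terminal low-information columns from both ends.

    Maximal contiguous runs of columns with IC < ``min_ic`` are removed from
    each extremity; the core is never trimmed below length 4.  Idempotent.
    """
    ic = ic_profile(pwm)
    lo, hi = 0, pwm.length
    while lo < hi and ic[lo] < min_ic:
        lo += 1
    while hi > lo and ic[hi - 1] < min_ic:
        hi -= 1
    if hi - lo < 4:
        # refuse to trim below the minimum informative core
        span = hi - lo
        if span <= 0:
            raise ValueError(f"{pwm.name}: all columns below IC threshold")
        while hi - lo < 4 and (lo > 0 or hi < pwm.length):
            if lo > 0:
                lo -= 1
            elif hi < pwm.length:
                hi += 1
    if lo == 0 and hi == pwm.length:
        return pwm
    return replace(pwm, matrix=pwm.matrix[:, lo:hi])


def _column_correlations(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of aligned probability columns (4-vectors).

    Zero-variance columns (uniform) are handled by convention: identical
    columns correlate 1, otherwise 0.
    """
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    na = np.sqrt((ac**2).sum(axis=0))
    nb = np.sqrt((bc**2).sum(axis=0))
    denom = na * nb
    num = (ac * bc).sum(axis=0)
    out = np.zeros(a.shape[1])
    ok = denom > 1e-12
    out[ok] = num[ok] / denom[ok]
    both_flat = ~ok & (na <= 1e-12) & (nb <= 1e-12)
    out[both_flat & np.all(np.abs(a - b) < 1e-9, axis=0)] = 1.0
    return out


def pwm_similarity(a: PWM, b: PWM) -> float:
    """Ungapped alignment similarity in [−1, 1].

    Maximum over all offsets with overlap ≥ max(5, ⌈0.75·min(L_a, L_b)⌉) and
    over ``b`` vs its reverse complement of the mean column-wise Pearson
    correlation between probability columns.
    """
    la, lb = a.length, b.length
    min_overlap = max(5, int(np.ceil(0.75 * min(la, lb))))
    if min_overlap > min(la, lb):
        raise ValueError("no admissible offset: motifs too short for overlap gate")
    best = -np.inf
    for bm in (b.matrix, b.reverse_complement().matrix):
        # offset = position of b's first column relative to a's first column
        for off in range(-(lb - min_overlap), la - min_overlap + 1):
            a_lo, a_hi = max(0, off), min(la, off + lb)
            if a_hi - a_lo < min_overlap:
                continue
            cols_a = a.matrix[:, a_lo:a_hi]
            cols_b = bm[:, a_lo - off : a_hi - off]
            score = _column_correlations(cols_a, cols_b).mean()
            best = max(best, score)
    return float(best)


def dedup_motifs(
    pwms: list[PWM], threshold: float = 0.8
) -> tuple[list[PWM], dict[str, str]]:
    """Collapse redundant motifs; keep the lowest discovery p per component.

    Builds a graph over motif pairs with similarity > ``threshold``; within
    each connected component the motif with the smallest discovery p-value is
    retained (ties broken by name).  Returns the retained motifs and a map
    from every input name to its representative's name.
    """
    n = len(pwms)
    if n == 0:
        return [], {}
    adj = sparse.lil_matrix((n, n), dtype=np.int8)
    for i in range(n):
        for j in range(i + 1, n):
            if pwm_similarity(pwms[i], pwms[j]) > threshold:
                adj[i, j] = 1
    _, labels = connected_components(adj.tocsr(), directed=False)
    kept: list[PWM] = []
    redundancy: dict[str, str] = {}
    for comp in np.unique(labels):
        members = [pwms[i] for i in np.flatnonzero(labels == comp)]
        rep = min(members, key=lambda m: (m.discovery_p, m.name))
        kept.append(rep)
        for m in members:
            redundancy[m.name] = rep.name
    kept.sort(key=lambda m: m.name)
    return kept, redundancy


def _encode(seq: str) -> np.ndarray:
    idx = np.full(len(seq), -1, dtype=int)
    for i, base in enumerate(ALPHABET):
        idx[np.frombuffer(seq.upper().encode(), dtype=np.uint8) == ord(base)] = i
    return idx


def scan_motifs(
    pwms: list[PWM],
    sequences: dict[str, str] | None = None,
    truth_hits: pd.DataFrame | None = None,
    background: np.ndarray | None = None,
    pseudocount: float = 0.01,
    score_fraction: float = 0.8,
) -> pd.DataFrame:
    """Binary peak × motif hit matrix from sequences or planted truth.

    With sequences: a hit is called when the best log-odds score (vs a
    0-order background, probabilities floored by ``pseudocount``) on either
    strand reaches ``score_fraction`` of the motif's maximum attainable
    score.  With ``truth_hits`` the planted matrix is passed through.
    """
    if truth_hits is not None:
        return truth_hits.astype(bool)
    if sequences is None:
        raise ValueError("provide either sequences or truth_hits")
    bg = background if background is not None else np.full(4, 0.25)
    names = list(sequences)
    hit = pd.DataFrame(False, index=names, columns=[p.name for p in pwms])
    for p in pwms:
        logodds = np.log2((p.matrix + pseudocount) / (p.matrix + pseudocount).sum(0)) - np.log2(
            bg[:, None]
        )
        max_score = logodds.max(axis=0).sum()
        thresh = score_fraction * max_score
        for strand_m in (logodds, logodds[_COMP][:, ::-1]):
            L = strand_m.shape[1]
            for sname, seq in sequences.items():
                if len(seq) < L:
                    continue
                idx = _encode(seq)
                best = -np.inf
                for start in range(len(seq) - L + 1):
                    window = idx[start : start + L]
                    if np.any(window < 0):  # N or other ambiguity: skip window
                        continue
                    best = max(best, strand_m[window, np.arange(L)].sum())
                if best >= thresh:
                    hit.loc[sname, p.name] = True
    return hit


@dataclass
class DeviationResult:
    """Motifs × cells bias-corrected deviation z-scores."""

    z: pd.DataFrame
    raw: pd.DataFrame
    n_background: int
    flags: pd.Series  # per-motif: "", "zero_peaks", "zero_background_sd"


def motif_deviations(
    counts: sparse.spmatrix,
    peak_ids: list[str],
    cell_ids: list[str],
    hits: pd.DataFrame,
    peak_gc: pd.Series,
    n_background: int = 50,
    seed: int = 0,
) -> DeviationResult:
    """chromVAR-style per-cell motif accessibility deviations.

    For motif m and cell c the expected count is
    ``depth_c × (Σ_{p∈m} total_p / Σ_p total_p)`` and the raw deviation is
    ``(observed − expected)/expected``.  Bias correction draws
    ``n_background`` matched peak sets of the same size, sampling for each
    member peak a nearest neighbor in z-scored (GC, log mean accessibility)
    space; z = (raw − mean_bg)/sd_bg.
    """
    X = sparse.csr_matrix(counts)  # peaks × cells
    n_peaks, n_cells = X.shape
    if len(peak_ids) != n_peaks:
        raise ValueError("peak_ids length mismatch")
    hits = hits.reindex(index=peak_ids).fillna(False)
    H = hits.to_numpy(dtype=float)  # peaks × motifs
    motif_names = list(hits.columns)

    totals_p = np.asarray(X.sum(axis=1)).ravel()
    depth_c = np.asarray(X.sum(axis=0)).ravel()
    grand = totals_p.sum()
    if grand == 0:
        raise ValueError("all-zero count matrix")

    # matched background neighborhoods in (GC, log mean accessibility) space
    feat = np.column_stack(
        [peak_gc.reindex(peak_ids).to_numpy(), np.log1p(totals_p / n_cells)]
    )
    feat = (feat - feat.mean(0)) / np.maximum(feat.std(0), 1e-9)
    k = min(n_peaks, 51)
    nn = NearestNeighbors(n_neighbors=k).fit(feat)
    neighbor_idx = nn.kneighbors(feat, return_distance=False)[:, 1:] if k > 1 else None

    rng = np.random.default_rng(seed)

    def raw_dev(indicator: np.ndarray) -> np.ndarray:
        # indicator: peaks × sets; returns sets × cells
        obs = indicator.T @ X  # sets × cells
        frac = indicator.T @ totals_p / grand  # per set
        expected = np.outer(frac, depth_c)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(expected > 0, (np.asarray(obs) - expected) / expected, 0.0)

    raw = raw_dev(H)  # motifs × cells

    flags = pd.Series("", index=motif_names)
    z = np.full_like(raw, np.nan)
    sizes = H.sum(axis=0).astype(int)
    for mi, mname in enumerate(motif_names):
        s = sizes[mi]
        if s == 0:
            flags[mname] = "zero_peaks"
            continue
        members = np.flatnonzero(H[:, mi] > 0)
        bg_sets = np.zeros((n_peaks, n_background))
        for b in range(n_background):
            if neighbor_idx is None:
                picks = members
            else:
                picks = neighbor_idx[members, rng.integers(0, neighbor_idx.shape[1], size=s)]
            np.add.at(bg_sets[:, b], picks, 1.0)
        bg_raw = raw_dev(bg_sets)  # n_background × cells
        mu = bg_raw.mean(axis=0)
        sd = bg_raw.std(axis=0, ddof=1)
        ok = sd > 1e-12
        if not ok.any():
            flags[mname] = "zero_background_sd"
            continue
        z[mi, ok] = (raw[mi, ok] - mu[ok]) / sd[ok]
        if not ok.all():
            flags[mname] = "zero_background_sd"
    return DeviationResult(
        z=pd.DataFrame(z, index=motif_names, columns=cell_ids),
        raw=pd.DataFrame(raw, index=motif_names, columns=cell_ids),
        n_background=n_background,
        flags=flags,
    )


def annotate_motifs(
    denovo: list[PWM],
    reference: list[PWM],
    rna: pd.DataFrame,
    deviations: pd.DataFrame,
    tf_of_reference: dict[str, str],
    k: int = 50,
    n: int = 400,
    k_small: int = 20,
    n_small: int = 200,
    small_threshold: int = 500,
    similarity_min: float = 0.6,
    expression_min_fraction: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Annotate de-novo motifs with candidate TFs.

    Candidates are reference motifs with similarity ≥ ``similarity_min`` whose
    TF is detected in ≥ ``expression_min_fraction`` of cells.  ``n`` aggregates
    of ``k`` cells each (uniform with replacement; small populations use
    ``k_small``/``n_small``) are formed over the cells shared by ``rna``
    (genes × cells, normalized) and ``deviations`` (motifs × cells); each
    candidate is scored by the Spearman correlation between aggregate mean
    motif deviation and aggregate mean TF expression, ranked by rho then
    similarity then name.
    """
    cells = [c for c in deviations.columns if c in set(rna.columns)]
    if not cells:
        raise ValueError("no shared cells between rna and deviations")
    if len(cells) < small_threshold:
        k, n = k_small, n_small
    rng = np.random.default_rng(seed)
    groups = rng.integers(0, len(cells), size=(n, k))
    dev_arr = deviations[cells].to_numpy()
    rna_arr = rna[cells].to_numpy()
    dev_agg = np.stack([np.nanmean(dev_arr[:, g], axis=1) for g in groups], axis=1)
    rna_agg = np.stack([rna_arr[:, g].mean(axis=1) for g in groups], axis=1)
    rna_agg = pd.DataFrame(rna_agg, index=rna.index)

    detected_fraction = (rna[cells] > 0).mean(axis=1)
    rows = []
    for dn in denovo:
        di = list(deviations.index).index(dn.name) if dn.name in deviations.index else None
        candidates = []
        for ref in reference:
            tf = tf_of_reference.get(ref.name)
            if tf is None or tf not in rna.index:
                continue
            sim = pwm_similarity(dn, ref)
            if sim < similarity_min:
                continue
            if detected_fraction[tf] < expression_min_fraction:
                continue
            if di is None:
                rho = np.nan
            else:
                rho = stats.spearmanr(dev_agg[di], rna_agg.loc[tf]).statistic
            candidates.append((tf, ref.name, sim, float(detected_fraction[tf]), rho))
        if not candidates:
            rows.append({"motif": dn.name, "tf": None, "reference": None,
                         "similarity": np.nan, "expression_fraction": np.nan,
                         "rho": np.nan, "rank": np.nan,
                         "reason": "no_candidate_passed_gates"})
            continue
        candidates.sort(key=lambda c: (-(c[4] if np.isfinite(c[4]) else -np.inf), -c[2], c[0]))
        for rank, (tf, refname, sim, frac, rho) in enumerate(candidates, start=1):
            rows.append({"motif": dn.name, "tf": tf, "reference": refname,
                         "similarity": sim, "expression_fraction": frac,
                         "rho": rho, "rank": rank, "reason": ""})
    return pd.DataFrame(rows)


def context_similarity_groups(
    motifs_by_tf: dict[str, list[PWM]],
    min_ic: float = 0.25,
) -> tuple[pd.DataFrame, float, float]:
    """Cross-lineage similarity of same-TF motifs, mesenchymal vs not.

    For each TF annotated in multiple lineages, all pairwise similarities of
    the trimmed matrices are computed and labeled by the motifs' context flag
    (both mesenchymal → 'mesenchymal', both non-mesenchymal →
    'non_mesenchymal'; mixed pairs are dropped).  The two groups are compared
    with a two-sided Mann–Whitney test.
    """
    rows = []
    for tf, group in motifs_by_tf.items():
        trimmed = [trim_pwm(m, min_ic) for m in group]
        for i in range(len(trimmed)):
            for j in range(i + 1, len(trimmed)):
                mi = group[i].context.get("mesenchymal")
                mj = group[j].context.get("mesenchymal")
                if mi is None or mj is None or mi != mj:
                    continue
                rows.append({
                    "tf": tf,
                    "motif_a": group[i].name,
                    "motif_b": group[j].name,
                    "group": "mesenchymal" if mi else "non_mesenchymal",
                    "similarity": pwm_similarity(trimmed[i], trimmed[j]),
                })
    df = pd.DataFrame(rows)
    mes = df.loc[df["group"] == "mesenchymal", "similarity"].to_numpy()
    non = df.loc[df["group"] == "non_mesenchymal", "similarity"].to_numpy()
    if len(mes) == 0 or len(non) == 0:
        raise ValueError("one context group is empty")
    if np.all(mes == mes[0]) and np.all(non == mes[0]):
        return df, np.nan, np.nan
    u, p = stats.mannwhitneyu(mes, non, alternative="two-sided")
    return df, float(u), float(p)
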