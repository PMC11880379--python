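"""Normalization, variable-feature selection, module scoring and pseudobulk
Spearman co-clustering.

Convention: count and normalized matrices are features × cells
(:class:`scipy.sparse` or dense :class:`numpy.ndarray`), with feature and
cell identifiers carried separately.  Pseudobulk profiles are features ×
groups DataFrames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.cluster import hierarchy
from statsmodels.nonparametric.smoothers_lowess import lowess


def normalize_log(counts, scale: float = 1e4):
    """Depth-normalize and log-transform: ln(1 + scale · count / cell_total).

    Cells with zero total counts are rejected (they carry no information and
    would divide by zero).
    """
    X = sparse.csc_matrix(counts, dtype=float)
    totals = np.asarray(X.sum(axis=0)).ravel()
    if np.any(totals == 0):
        bad = np.flatnonzero(totals == 0)
        raise ValueError(f"cells with zero total counts at positions {bad[:10].tolist()}")
    Y = X.multiply(scale / totals[None, :]).tocsc()
    Y.data = np.log1p(Y.data)
    return Y


def select_hvg(normalized, feature_ids: list[str], clip: bool = True) -> list[str]:
    """Highly variable features by standardized variance above median + MAD.

    Each feature's variance is standardized by its trend-predicted standard
    deviation (lowess regression of log10 variance on log10 mean across
    features), values clipped at sqrt(n_cells); features whose standardized
    variance exceeds the median plus the (unscaled) median absolute deviation
    over all features are returned.
    """
    X = sparse.csr_matrix(normalized, dtype=float)
    n_feat, n_cells = X.shape
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    if n_feat < 2:
        raise ValueError("need at least 2 features to fit a mean-variance trend")
    mu = np.asarray(X.mean(axis=1)).ravel()
    ex2 = np.asarray(X.multiply(X).mean(axis=1)).ravel()
    var = (ex2 - mu**2) * n_cells / (n_cells - 1)
    ok = (var > 0) & (mu > 0)
    if not ok.any():
        warnings.warn("constant matrix: no variable features")
        return []
    log_mu, log_var = np.log10(mu[ok]), np.log10(var[ok])
    fit = lowess(log_var, log_mu, frac=0.5, return_sorted=False)
    sd_pred = np.sqrt(10**fit)

    std_var = np.zeros(n_feat)
    rows = np.flatnonzero(ok)
    cap = np.sqrt(n_cells)
    for pos, (i, sd) in enumerate(zip(rows, sd_pred)):
        x = np.asarray(X[i].todense()).ravel()
        z = (x - mu[i]) / sd
        if clip:
            z = np.clip(z, -cap, cap)
        std_var[i] = np.sum((z - z.mean())**2) / (n_cells - 1)

    vals = std_var[rows]
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    selected = rows[vals > med + mad]
    return [feature_ids[i] for i in selected]


def score_module(
    normalized,
    feature_ids: list[str],
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell module score: module mean minus expression-matched control mean.

    Control genes are drawn (``n_ctrl`` per module gene, with replacement)
    from the same average-expression bin, with genes partitioned into
    ``n_bins`` equal-frequency bins by their mean normalized expression.
    """
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    index = {g: i for i, g in enumerate(feature_ids)}
    missing = [g for g in gene_set if g not in index]
    if missing:
        raise ValueError(f"module genes missing from features: {missing[:5]}")
    X = sparse.csr_matrix(normalized, dtype=float)
    mu = np.asarray(X.mean(axis=1)).ravel()
    n_bins = min(n_bins, len(feature_ids))
    ranks = stats.rankdata(mu, method="ordinal") - 1
    bins = (ranks * n_bins // len(mu)).astype(int)
    rng = np.random.default_rng(seed)

    module_rows = np.array([index[g] for g in gene_set])
    ctrl_rows = []
    for r in module_rows:
        pool = np.flatnonzero(bins == bins[r])
        ctrl_rows.append(rng.choice(pool, size=n_ctrl, replace=True))
    ctrl_rows = np.concatenate(ctrl_rows)

    module_mean = np.asarray(X[module_rows].mean(axis=0)).ravel()
    ctrl_mean = np.asarray(X[ctrl_rows].mean(axis=0)).ravel()
    return module_mean - ctrl_mean


def pseudobulk_means(normalized, feature_ids: list[str], labels: pd.Series) -> pd.DataFrame:
    """Per-group arithmetic mean of normalized values (features × groups)."""
    X = sparse.csc_matrix(normalized, dtype=float)
    if X.shape[1] != len(labels):
        raise ValueError("labels must cover every cell")
    if labels.isna().any():
        raise ValueError("every cell must be labeled")
    groups = sorted(labels.unique())
    out = {}
    lab = labels.to_numpy()
    for g in groups:
        cols = np.flatnonzero(lab == g)
        if len(cols) == 0:
            raise ValueError(f"empty group {g}")
        out[g] = np.asarray(X[:, cols].mean(axis=1)).ravel()
    return pd.DataFrame(out, index=feature_ids)


@dataclass
class CorrelationClustering:
    """Pairwise Spearman matrix with an average-linkage dendrogram."""

    rho: pd.DataFrame
    linkage: np.ndarray
    labels: list[str]
    dropped: list[str]

    def newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

        return rec(tree) + ";"

    def clades(self) -> list[frozenset]:
        """Leaf-label sets of every internal node."""
        n = len(self.labels)
        members = {i: frozenset([self.labels[i]]) for i in range(n)}
        out = []
        for k, (a, b, _, _) in enumerate(self.linkage):
            m = members[int(a)] | members[int(b)]
            members[n + k] = m
            out.append(m)
        return out

    def is_exclusive_clade(self, group: set[str]) -> bool:
        """True iff ``group`` is exactly the leaf set of some internal node."""
        return frozenset(group) in set(self.clades())


def correlate_and_cluster(
    profile: pd.DataFrame,
    feature_subset: list[str] | None = None,
) -> CorrelationClustering:
    """Spearman co-clustering of pseudobulk profiles.

    Rho is computed across the restricted feature set; agglomerative
    clustering uses average linkage on distance 1 − rho.  Constant profile
    columns (undefined ranks) are dropped with a warning.
    """
    P = profile if feature_subset is None else profile.loc[feature_subset]
    if P.shape[1] < 3:
        raise ValueError("need at least 3 groups")
    constant = P.columns[(P.nunique(axis=0) <= 1)].tolist()
    if constant:
        warnings.warn(f"dropping constant profile columns: {constant}")
        P = P.drop(columns=constant)
    rho = pd.DataFrame(
        stats.spearmanr(P.to_numpy()).statistic if P.shape[1] > 2
        else np.corrcoef(stats.rankdata(P, axis=0).T),
        index=P.columns, columns=P.columns,
    )
    dist = 1.0 - rho.to_numpy()
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    return CorrelationClustering(rho=rho, linkage=Z, labels=list(P.columns), dropped=constant)
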