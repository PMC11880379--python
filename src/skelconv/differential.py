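"""Logistic-regression marker testing with latent covariates.

The same test backs differentially expressed genes (RNA), differentially
accessible peaks (ATAC) and differential motif activity: per feature, group
membership is regressed on the feature value plus latent covariates, and the
feature's contribution is assessed by a 1-df likelihood-ratio chi-square
against the covariate-only null.

The per-feature fits share the covariate columns, so Newton iterations are
vectorized across features (stacked design tensors, batched solves); the
covariate-only null is fitted once.  `statsmodels.Logit` on individual
features is used as an independent cross-check in the test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse, stats


def _sigmoid(eta):
    return 0.5 * (1.0 + np.tanh(0.5 * eta))


def _fit_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 0.0,
                  max_iter: int = 50, tol: float = 1e-8):
    """Newton-Raphson fit; returns (beta, loglike, converged)."""
    n, k = X.shape
    beta = np.zeros(k)
    pen = ridge * np.eye(k)
    pen[0, 0] = 0.0
    for _ in range(max_iter):
        eta = X @ beta
        p = _sigmoid(eta)
        W = np.maximum(p * (1 - p), 1e-10)
        g = X.T @ (y - p) - pen @ beta
        H = (X * W[:, None]).T @ X + pen
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return beta, -np.inf, False
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = np.clip(X @ beta, -35, 35)
    ll = np.sum(y * eta - np.log1p(np.exp(eta)))
    converged = np.max(np.abs(step)) < 1e-4 and np.max(np.abs(beta)) < 30
    return beta, ll, converged


def _batched_logistic(designs: np.ndarray, y: np.ndarray, ridge: float = 0.0,
                      max_iter: int = 50, tol: float = 1e-8):
    """Newton fits for F designs sharing the response.

    designs: (F, n, k); returns (beta (F,k), loglike (F,), converged (F,)).
    """
    F, n, k = designs.shape
    beta = np.zeros((F, k))
    eye = np.eye(k) * ridge
    eye[0, 0] = 0.0
    active = np.ones(F, dtype=bool)
    step_max = np.full(F, np.inf)
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        Xa = designs[idx]
        eta = np.einsum("fnk,fk->fn", Xa, beta[idx])
        p = _sigmoid(eta)
        W = np.maximum(p * (1 - p), 1e-10)
        g = np.einsum("fnk,fn->fk", Xa, (y[None, :] - p)) - beta[idx] @ eye
        H = np.einsum("fnk,fn,fnl->fkl", Xa, W, Xa) + eye[None, :, :]
        try:
            step = np.linalg.solve(H, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.stack([np.linalg.lstsq(H[i], g[i], rcond=None)[0] for i in range(len(idx))])
        beta[idx] += step
        sm = np.max(np.abs(step), axis=1)
        step_max[idx] = sm
        active[idx] = sm >= tol
    eta = np.clip(np.einsum("fnk,fk->fn", designs, beta), -35, 35)
    ll = np.sum(y[None, :] * eta - np.log1p(np.exp(eta)), axis=1)
    converged = (step_max < 1e-4) & (np.max(np.abs(beta), axis=1) < 30)
    return beta, ll, converged


def lr_markers(
    normalized,
    feature_ids: list[str],
    group_mask: np.ndarray,
    latent_covariates: np.ndarray | None = None,
    min_pct: float = 0.1,
    logfc_min: float = 0.5,
    alpha: float = 0.05,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Likelihood-ratio marker test of a cell group against the rest.

    Parameters
    ----------
    normalized
        Features × cells matrix of depth-normalized log values.
    group_mask
        Boolean per-cell membership of the foreground group.
    latent_covariates
        Optional cells × p matrix of nuisance covariates (e.g. depth, stage)
        included in both the full and the null model.
    adjust
        'bonferroni' (default) or 'bh'.

    Returns a table with ``log_fc`` (natural-log fold change of de-logged
    means with pseudocount 1), ``pct_in``/``pct_out``, raw and adjusted p,
    and ``pass``; features below the ``min_pct`` detection gate in both
    groups carry NaN p-values.  Non-converged (separated) fits are re-fit
    with a small ridge penalty and flagged.
    """
    X = sparse.csr_matrix(normalized, dtype=float)
    n_feat, n_cells = X.shape
    y = np.asarray(group_mask, dtype=float)
    if y.sum() == 0 or y.sum() == n_cells:
        raise ValueError("group mask must be non-trivial")
    if latent_covariates is None:
        C = np.ones((n_cells, 1))
    else:
        L = np.atleast_2d(np.asarray(latent_covariates, dtype=float))
        if L.shape[0] != n_cells:
            L = L.T
        C = np.column_stack([np.ones(n_cells), L])

    in_mask = y.astype(bool)
    pct_in = np.asarray((X[:, in_mask] > 0).mean(axis=1)).ravel()
    pct_out = np.asarray((X[:, ~in_mask] > 0).mean(axis=1)).ravel()
    tested = (pct_in >= min_pct) | (pct_out >= min_pct)

    Xd = np.asarray(X.todense())
    mean_in = np.expm1(Xd[:, in_mask]).mean(axis=1)
    mean_out = np.expm1(Xd[:, ~in_mask]).mean(axis=1)
    log_fc = np.log((mean_in + 1) / (mean_out + 1))

    p_raw = np.full(n_feat, np.nan)
    flags = np.array([""] * n_feat, dtype=object)

    _, ll0, _ = _fit_logistic(C, y)
    t_idx = np.flatnonzero(tested)
    if t_idx.size:
        designs = np.empty((t_idx.size, n_cells, C.shape[1] + 1))
        designs[:, :, 0] = 1.0
        designs[:, :, 1] = Xd[t_idx]
        designs[:, :, 2:] = C[None, :, 1:]
        _, ll1, conv = _batched_logistic(designs, y)
        bad = ~conv
        if bad.any():
            _, ll1b, _ = _batched_logistic(designs[bad], y, ridge=1e-3)
            ll1[bad] = ll1b
            for j in np.flatnonzero(bad):
                flags[t_idx[j]] = "separation_penalized"
        lr = np.maximum(2.0 * (ll1 - ll0), 0.0)
        p_raw[t_idx] = stats.chi2.sf(lr, df=1)

    p_adj = np.full(n_feat, np.nan)
    m = t_idx.size
    if m:
        if adjust == "bonferroni":
            p_adj[t_idx] = np.minimum(p_raw[t_idx] * m, 1.0)
        elif adjust == "bh":
            p_adj[t_idx] = bh_adjust(p_raw[t_idx])
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")

    passed = (p_adj < alpha) & (log_fc > logfc_min) & tested
    return pd.DataFrame(
        {
            "feature": feature_ids,
            "log_fc": log_fc,
            "pct_in": pct_in,
            "pct_out": pct_out,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "pass": passed,
            "flag": flags,
        }
    ).set_index("feature")


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def common_markers(tables: list[pd.DataFrame]) -> set[str]:
    """Intersection of passing features across per-lineage marker tables."""
    if len(tables) == 0:
        raise ValueError("need at least one marker table")
    sets = [set(t.index[t["pass"]]) for t in tables]
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out
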