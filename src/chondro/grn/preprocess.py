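"""Quantile normalization and empirical-Bayes batch correction."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix

__all__ = ["quantile_normalize", "correct_batch"]


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the mean order-statistic distribution.

    Ties within a column receive the average of the reference values at the
    tied ranks (fractional average ranks interpolate between the two
    neighboring order statistics).
    """
    if m.n_samples < 2:
        raise ValueError("quantile normalization requires at least 2 samples")
    if m.n_genes == 0:
        raise ValueError("empty expression matrix")
    X = m.values.to_numpy(dtype=float)
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        ranks = stats.rankdata(X[:, j], method="average")
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (ref[lo] + ref[hi])
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return m.with_values(values)


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(Z_b, g_hat, d_hat, g_bar, t2, a, b, conv=1e-10, max_iter=10_000):
    """Iterative solution for the parametric empirical-Bayes batch estimates."""
    n = Z_b.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((Z_b - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.abs(g_new - g_old).max() / max(np.abs(g_old).max(), 1e-12),
            np.abs(d_new - d_old).max() / max(np.abs(d_old).max(), 1e-12),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def correct_batch(m: ExpressionMatrix) -> ExpressionMatrix:
    """Remove per-batch location/scale effects with empirical-Bayes shrinkage.

    Per gene, the data are standardized against the size-weighted grand
    mean and pooled variance, batch location/scale deviations are estimated
    and shrunk toward their across-gene priors (normal prior on locations,
    inverse-gamma on scales), and the adjusted values are returned on the
    original scale.  Per-gene pooled means are restored exactly.  A
    single-batch matrix is returned unchanged; a matrix with no within-batch
    variance anywhere is adjusted by batch-mean alignment alone.
    """
    if m.batch is None:
        raise ValueError("correct_batch requires batch labels")
    batches = list(dict.fromkeys(m.batch))
    if len(batches) == 1:
        return m.with_values(m.values.copy())
    X = m.values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    members = {b: np.flatnonzero((m.batch == b).to_numpy()) for b in batches}
    for b, idx in members.items():
        if len(idx) < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")

    sizes = np.array([len(members[b]) for b in batches], dtype=float)
    batch_means = np.stack([X[:, members[b]].mean(axis=1) for b in batches], axis=1)
    alpha = batch_means @ (sizes / n_samples)

    fitted = np.empty_like(X)
    for k, b in enumerate(batches):
        fitted[:, members[b]] = batch_means[:, k][:, None]
    var_pooled = ((X - fitted) ** 2).mean(axis=1)

    if var_pooled.max() < 1e-12:
        out = X - fitted + alpha[:, None]
        return m.with_values(pd.DataFrame(out, index=m.values.index, columns=m.values.columns))

    sd = np.sqrt(np.maximum(var_pooled, 1e-12))
    Z = (X - alpha[:, None]) / sd[:, None]

    out = np.empty_like(X)
    for k, b in enumerate(batches):
        idx = members[b]
        Z_b = Z[:, idx]
        g_hat = Z_b.mean(axis=1)
        d_hat = Z_b.var(axis=1, ddof=1)
        g_bar = g_hat.mean()
        t2 = g_hat.var(ddof=1)
        d_mean = d_hat.mean()
        d_var = d_hat.var(ddof=1)
        if t2 < 1e-12 or d_var < 1e-24 or d_mean < 1e-12:
            # Degenerate priors (e.g. noise-free genes): use the per-gene
            # estimates directly instead of empirical-Bayes shrinkage.
            g_star, d_star = g_hat, np.maximum(d_hat, 1e-12)
        else:
            a_prior = (2.0 * d_var + d_mean**2) / d_var
            b_prior = (d_mean * d_var + d_mean**3) / d_var
            g_star, d_star = _it_sol(Z_b, g_hat, np.maximum(d_hat, 1e-12), g_bar, t2, a_prior, b_prior)
        out[:, idx] = (Z_b - g_star[:, None]) / np.sqrt(np.maximum(d_star, 1e-12))[:, None]

    out = out * sd[:, None] + alpha[:, None]
    out += (alpha - out.mean(axis=1))[:, None]  # restore pooled gene means exactly
    return m.with_values(pd.DataFrame(out, index=m.values.index, columns=m.values.columns))
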