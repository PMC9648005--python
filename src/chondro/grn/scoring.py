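"""Three edge-scoring algorithms for TF -> target inference.

* ``mi_dpi`` — pairwise mutual information (equal-frequency rank binning,
  Miller-Madow corrected) pruned with the data-processing inequality over
  regulator-mediated triangles.
* ``tree_importance`` — per-target regression-forest importances of the TF
  predictors.
* ``stability_regression`` — selection frequency of TFs along subsampled,
  reweighted L1 regularization paths.

All scorers return nonnegative TF x gene matrices with self-edges undefined
(NaN) and are deterministic given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import ExtraTreesRegressor
from sklearn.linear_model import lars_path

from .expression import ExpressionMatrix

__all__ = ["EdgeScoreMatrix", "score_edges", "METHODS"]

METHODS = ("mi_dpi", "tree_importance", "stability_regression")


@dataclass
class EdgeScoreMatrix:
    """TF x gene score matrix for one method (self-scores are NaN)."""

    scores: pd.DataFrame
    method: str

    @property
    def tfs(self) -> list:
        return list(self.scores.index)

    @property
    def genes(self) -> list:
        return list(self.scores.columns)

    def finite_values(self) -> np.ndarray:
        vals = self.scores.to_numpy(dtype=float).ravel()
        return vals[np.isfinite(vals)]


def _check_inputs(m: ExpressionMatrix, tfs) -> list:
    tfs = list(tfs)
    missing = set(tfs) - set(m.genes)
    if missing:
        raise ValueError(f"TFs not present in the matrix: {sorted(missing)}")
    if m.n_samples < 10:
        raise ValueError("edge scoring requires at least 10 samples")
    return tfs


def _warn_constant(m: ExpressionMatrix) -> np.ndarray:
    X = m.values.to_numpy(dtype=float)
    constant = X.std(axis=1) == 0
    if constant.any():
        names = [g for g, c in zip(m.genes, constant) if c]
        warnings.warn(f"constant genes scored 0: {names}", stacklevel=3)
    return constant


def score_edges(
    m: ExpressionMatrix,
    tfs,
    method: str,
    seed: int | None = None,
    **params,
) -> EdgeScoreMatrix:
    """Score all TF -> gene edges with one of :data:`METHODS`."""
    tfs = _check_inputs(m, tfs)
    if method == "mi_dpi":
        scores = _score_mi_dpi(m, tfs, **params)
    elif method == "tree_importance":
        scores = _score_trees(m, tfs, seed=seed, **params)
    elif method == "stability_regression":
        scores = _score_stability(m, tfs, seed=seed, **params)
    else:
        raise ValueError(f"unknown scoring method {method!r}")
    for tf in tfs:
        if tf in scores.columns:
            scores.loc[tf, tf] = np.nan
    return EdgeScoreMatrix(scores=scores, method=method)


# ---------------------------------------------------------------------------
# mutual information + DPI
# ---------------------------------------------------------------------------


def _discretize(X: np.ndarray, n_bins: int) -> np.ndarray:
    n = X.shape[1]
    disc = np.empty_like(X, dtype=np.intp)
    for i in range(X.shape[0]):
        ranks = stats.rankdata(X[i], method="average") - 1.0
        disc[i] = np.minimum((ranks * n_bins / n).astype(np.intp), n_bins - 1)
    return disc


def _pair_mi(a: np.ndarray, b: np.ndarray, n_bins: int) -> float:
    n = a.shape[0]
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (a, b), 1.0)
    joint /= n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    plugin = float((joint[nz] * np.log(joint[nz] / np.outer(pa, pb)[nz])).sum())
    # Miller-Madow bias correction for the plug-in estimator.
    bias = (nz.sum() - (pa > 0).sum() - (pb > 0).sum() + 1) / (2.0 * n)
    return max(0.0, plugin - bias)


def _score_mi_dpi(m: ExpressionMatrix, tfs, n_bins: int | None = None, dpi_tolerance: float = 0.15):
    _warn_constant(m)
    X = m.values.to_numpy(dtype=float)
    genes = m.genes
    n = m.n_samples
    # Cube-root binning keeps the plug-in MI bias ((B-1)^2 / 2n) small.
    n_bins = n_bins or max(2, int(round(n ** (1.0 / 3.0))))
    disc = _discretize(X, n_bins)
    g = len(genes)
    mi = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            mi[i, j] = mi[j, i] = _pair_mi(disc[i], disc[j], n_bins)
    # DPI, restricted to regulator-mediated paths: a TF->gene edge is
    # dropped when some *other TF* connects more strongly to both endpoints
    # (with a multiplicative tolerance).  Using arbitrary genes as
    # intermediates would let co-regulated siblings prune their own true
    # regulator in TF-restricted inference.
    index = {gene: k for k, gene in enumerate(genes)}
    tf_idx = [index[tf] for tf in tfs]
    keep = mi.copy()
    for i in tf_idx:
        for j in range(g):
            if j == i or mi[i, j] <= 0:
                continue
            thr = mi[i, j] * (1.0 + dpi_tolerance)
            mediators = [k for k in tf_idx if k not in (i, j)]
            if mediators and np.any(np.minimum(mi[i, mediators], mi[j, mediators]) > thr):
                keep[i, j] = 0.0
    rows = [keep[index[tf]] for tf in tfs]
    return pd.DataFrame(np.asarray(rows), index=list(tfs), columns=genes)


# ---------------------------------------------------------------------------
# regression forests
# ---------------------------------------------------------------------------


def _score_trees(
    m: ExpressionMatrix,
    tfs,
    seed=None,
    n_trees: int = 100,
    max_features: str | float = "sqrt",
    min_samples_leaf: int = 20,
):
    _warn_constant(m)
    X = m.values.to_numpy(dtype=float)
    genes = m.genes
    index = {gene: k for k, gene in enumerate(genes)}
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(genes))
    scores = pd.DataFrame(0.0, index=list(tfs), columns=genes)
    for gi, gene in enumerate(genes):
        predictors = [tf for tf in tfs if tf != gene]
        if not predictors:
            continue
        y = X[index[gene]]
        if y.std() == 0:
            continue
        y = (y - y.mean()) / y.std()
        Xp = X[[index[tf] for tf in predictors]].T
        forest = ExtraTreesRegressor(
            n_estimators=n_trees,
            max_features=max_features,
            min_samples_leaf=min_samples_leaf,
            random_state=np.random.default_rng(children[gi]).integers(2**31 - 1),
            n_jobs=1,
        )
        forest.fit(Xp, y)
        # Unnormalized importances (mean impurity reduction per tree) keep
        # targets unexplained by any TF at genuinely low scores.
        imp = np.mean(
            [t.tree_.compute_feature_importances(normalize=False) for t in forest.estimators_],
            axis=0,
        )
        for tf, value in zip(predictors, imp):
            scores.loc[tf, gene] = value
    return scores


# ---------------------------------------------------------------------------
# stability selection on L1 paths
# ---------------------------------------------------------------------------


def _score_stability(
    m: ExpressionMatrix,
    tfs,
    seed=None,
    n_resamples: int = 50,
    n_steps: int = 2,
    reweight_low: float = 0.2,
):
    _warn_constant(m)
    X = m.values.to_numpy(dtype=float)
    genes = m.genes
    index = {gene: k for k, gene in enumerate(genes)}
    n = m.n_samples
    half = n // 2
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(genes))
    scores = pd.DataFrame(0.0, index=list(tfs), columns=genes)
    for gi, gene in enumerate(genes):
        predictors = [tf for tf in tfs if tf != gene]
        if not predictors:
            continue
        y = X[index[gene]].astype(float)
        if y.std() == 0:
            continue
        Xp = X[[index[tf] for tf in predictors]].T.astype(float)
        sd = Xp.std(axis=0)
        sd[sd == 0] = 1.0
        Xp = (Xp - Xp.mean(axis=0)) / sd
        y = y - y.mean()
        rng = np.random.default_rng(children[gi])
        freq = np.zeros(len(predictors))
        for _ in range(n_resamples):
            rows = rng.choice(n, size=half, replace=False)
            weights = rng.uniform(reweight_low, 1.0, size=len(predictors))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, active, _ = lars_path(
                    Xp[rows] * weights, y[rows], method="lar", max_iter=n_steps
                )
            freq[active[:n_steps]] += 1.0
        freq /= n_resamples
        for tf, f in zip(predictors, freq):
            scores.loc[tf, gene] = f
    return scores
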