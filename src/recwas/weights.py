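"""Training per-SNP weights that link cis-genotypes to peak activity.

Three weight models, mirroring the training phase of predicted-activity
association studies:

* ``lasso`` — L1-penalized regression of activity on standardized
  genotypes; the penalty is picked by K-fold cross-validated mean squared
  error over a descending grid of 100 penalties from the smallest penalty
  producing the all-zero model down to 0.001 of it.  The solution path is
  computed exactly with least-angle regression (coefficients are piecewise
  linear in the penalty), so the grid is evaluated by interpolation rather
  than by refitting.
* ``marginal`` — per-SNP simple linear regression (slope, standard error,
  two-sided t-test with n-2 df) on standardized genotypes.
* ``top1`` — the single most significant marginal SNP carries its slope;
  everything else is zero.

All weights are reported on the standardized-genotype scale; prediction and
kernel code standardize identically, which keeps the weighted kernel
meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import lars_path, lasso_path

from .exceptions import DegenerateDataError, ParameterError
from .genio import GenotypeDataset, WeightVector
from ._utils import standardize_columns

__all__ = ["MarginalEffectTable", "train_lasso", "marginal_effects", "top1",
           "select_model"]


@dataclass
class MarginalEffectTable:
    """Per-SNP single-regressor OLS results on the standardized scale."""
    variant_ids: list
    positions: np.ndarray
    beta_hat: np.ndarray
    se: np.ndarray
    p_value: np.ndarray
    flagged: np.ndarray  # constant SNPs: beta forced to 0, p undefined

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "variant_id": self.variant_ids, "position": self.positions,
            "beta_hat": self.beta_hat, "se": self.se,
            "p_value": self.p_value, "flagged": self.flagged})


def _as_matrix(G):
    if isinstance(G, GenotypeDataset):
        return G.standardized(), G.variant_ids, G.positions
    G = np.asarray(G, dtype=float)
    ids = [f"snp{j + 1}" for j in range(G.shape[1])]
    pos = np.arange(1, G.shape[1] + 1)
    return standardize_columns(G), ids, pos


def _lasso_grid_fit(X, y_centered, grid):
    """Exact coefficients at each grid penalty via the LARS lasso path."""
    try:
        alphas, _, coefs = lars_path(X, y_centered, method="lasso")
    except np.linalg.LinAlgError:
        _, coefs, _ = lasso_path(X, y_centered, alphas=grid)
        return coefs
    # piecewise-linear interpolation onto the (descending) grid
    out = np.empty((X.shape[1], grid.size))
    for j in range(X.shape[1]):
        out[j] = np.interp(-grid, -alphas, coefs[j])
    return out


def train_lasso(G, C, cv_folds: int = 5, seed: int = 0, n_alphas: int = 100,
                alpha_min_ratio: float = 1e-3) -> WeightVector:
    """Cross-validated LASSO weights; the all-zero result is valid and
    flagged through ``WeightVector.is_null``."""
    X, ids, _ = _as_matrix(G)
    y = np.asarray(C, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ParameterError("activity length does not match samples")
    if n < 20:
        raise ParameterError("need at least 20 samples to cross-validate")
    if np.var(y) == 0.0:
        raise DegenerateDataError("constant peak activity")
    yc = y - y.mean()
    lam_max = float(np.abs(X.T @ yc).max()) / n
    if lam_max == 0.0:  # all SNPs constant
        return WeightVector(ids, np.zeros(p), "lasso")
    grid = np.geomspace(lam_max, lam_max * alpha_min_ratio, n_alphas)

    rng = np.random.default_rng(seed)
    folds = rng.permutation(n) % cv_folds
    fold_mse = np.zeros((cv_folds, n_alphas))
    for f in range(cv_folds):
        tr = folds != f
        ytr = y[tr]
        coefs = _lasso_grid_fit(X[tr], ytr - ytr.mean(), grid)
        pred = X[~tr] @ coefs + ytr.mean()
        fold_mse[f] = ((y[~tr, None] - pred) ** 2).mean(axis=0)
    mse = fold_mse.mean(axis=0)
    se = fold_mse.std(axis=0, ddof=1) / np.sqrt(cv_folds)
    # one-standard-error convention: the largest penalty whose CV error is
    # within one SE of the minimum; the grid starts at the all-zero model,
    # so a response carrying no signal resolves to the null model
    i_min = int(np.argmin(mse))
    within = np.flatnonzero(mse <= mse[i_min] + se[i_min])
    best = grid[int(within[0])]
    coefs = _lasso_grid_fit(X, yc, np.array([best, best * 0.999]))
    return WeightVector(ids, coefs[:, 0], "lasso")


def marginal_effects(G, C) -> MarginalEffectTable:
    """Per-SNP OLS slope of activity on one standardized SNP at a time."""
    X, ids, pos = _as_matrix(G)
    y = np.asarray(C, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ParameterError("activity length does not match samples")
    if n < 3:
        raise ParameterError("need at least 3 samples for a slope test")
    yc = y - y.mean()
    constant = ~np.any(X != 0.0, axis=0)  # standardized constants are 0
    # slope on unit-variance regressor: beta = X'y / n
    beta = X.T @ yc / n
    ssy = float(yc @ yc)
    rss = np.maximum(ssy - n * beta ** 2, 0.0)
    se = np.sqrt(rss / (n - 2) / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), n - 2)
    pvals = np.where(se == 0.0, 0.0, pvals)  # perfect fit
    beta = np.where(constant, 0.0, beta)
    pvals = np.where(constant, np.nan, pvals)
    se = np.where(constant, np.nan, se)
    return MarginalEffectTable(ids, np.asarray(pos), beta, se, pvals,
                               constant)


def top1(table: MarginalEffectTable) -> WeightVector:
    """Weight vector with the single most significant SNP's slope.

    Exact p ties break toward the smaller genomic position; an all-flagged
    table yields the null (all-zero) vector.
    """
    p = len(table.variant_ids)
    if p == 0:
        raise ParameterError("empty marginal table")
    w = np.zeros(p)
    pv = np.where(np.isnan(table.p_value), np.inf, table.p_value)
    if np.all(np.isinf(pv)):
        return WeightVector(table.variant_ids, w, "top1")
    order = np.lexsort((table.positions, pv))
    k = int(order[0])
    w[k] = table.beta_hat[k]
    return WeightVector(table.variant_ids, w, "top1")


def _oof_slope_p(y, pred):
    """P-value of the slope in the regression of y on out-of-fold
    predictions; constant predictions score p = 1."""
    if np.var(pred) == 0.0:
        return 1.0
    n = y.size
    r = float(np.corrcoef(y, pred)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def select_model(G, C, candidates=("lasso", "top1", "marginal"),
                 cv_folds: int = 5, seed: int = 0) -> WeightVector:
    """Pick the weight model with the most significant cross-validation
    p-value (observed activity regressed on out-of-fold predictions)."""
    allowed = {"lasso", "top1", "marginal"}
    if not set(candidates) <= allowed:
        raise ParameterError(f"candidates must be within {allowed}")
    if not candidates:
        raise ParameterError("no candidate models")
    X, ids, pos = _as_matrix(G)
    y = np.asarray(C, dtype=float).ravel()
    n = y.size
    rng = np.random.default_rng(seed)
    folds = rng.permutation(n) % cv_folds

    def fit_fold(name, tr):
        sub = X[tr]
        if name == "lasso":
            wv = train_lasso(sub, y[tr], cv_folds=cv_folds, seed=seed)
            return wv.weights
        table = marginal_effects(sub, y[tr])
        table.positions = np.asarray(pos)
        if name == "top1":
            return top1(table).weights
        return np.where(table.flagged, 0.0, table.beta_hat)

    best_name, best_p = None, np.inf
    for name in candidates:
        pred = np.zeros(n)
        try:
            for f in range(cv_folds):
                tr = folds != f
                pred[~tr] = X[~tr] @ fit_fold(name, tr)
        except DegenerateDataError:
            continue
        pv = _oof_slope_p(y, pred)
        if pv < best_p:
            best_name, best_p = name, pv
    if best_name is None:
        raise DegenerateDataError("all candidate models degenerate")
    if best_name == "lasso":
        wv = train_lasso(X, y, cv_folds=cv_folds, seed=seed)
        wv = WeightVector(ids, wv.weights, "lasso", cv_p=best_p)
    else:
        table = marginal_effects(X, y)
        table.variant_ids = ids
        table.positions = np.asarray(pos)
        if best_name == "top1":
            wv = top1(table)
            wv = WeightVector(ids, wv.weights, "top1", cv_p=best_p)
        else:
            w = np.where(table.flagged, 0.0, table.beta_hat)
            wv = WeightVector(ids, w, "marginal", cv_p=best_p)
    return wv
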