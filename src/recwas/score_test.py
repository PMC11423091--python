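"""Variance-component score test of a peak region (the random-effect test).

Model: trait Y on covariates Z (plus intercept) and region genotypes G,
with per-SNP effects treated as random, beta_k ~ N(0, w_k^2 * tau).  The
null hypothesis tau = 0 is tested with the score statistic

    Q = (Y - Yhat)' K (Y - Yhat),      K = G W G',  W = diag{w_1^2, ...}

where Yhat is fitted under the null (least squares for continuous traits,
logistic regression for dichotomous ones).  Under the null Q is a mixture
of 1-df chi-squares whose mixture weights are the eigenvalues of
P^(1/2) K P^(1/2) with P the null variance/projection operator; the p-value
comes from exact characteristic-function inversion (Davies), falling back
to the Liu moment approximation when the inversion fails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .chi2mix import pvalue_mixture_chisq
from .exceptions import DegenerateDataError, ParameterError
from .genio import GenotypeDataset, WeightVector, compute_maf
from .kernels import KernelMatrix, build_kernel, kernel_features

__all__ = ["NullModel", "AssociationResult", "fit_null_model",
           "score_statistic", "null_mixture_weights", "recwas_test"]

EIGEN_RTOL = 1e-10  # eigenvalues below EIGEN_RTOL * max are dropped


@dataclass
class AssociationResult:
    """One peak-trait association, comparable across methods."""
    peak_id: str
    method: str            # "cwas" or "recwas"
    kernel: str            # kernel name, or "linear-fixed" for CWAS
    statistic: float
    p_value: float
    n_snps_used: int
    pvalue_method: str | None = None
    testable: bool = True
    note: str = ""


@dataclass
class NullModel:
    """Trait model fitted under H0 (no regional genetic effect)."""
    trait_type: str
    alpha_hat: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    dispersion: np.ndarray | float  # sigma^2, or per-sample mu(1-mu)
    design: np.ndarray              # [1, Z]

    @property
    def n(self) -> int:
        return self.fitted.shape[0]


def _design(Y, covariates):
    Y = np.asarray(Y, dtype=float).ravel()
    n = Y.size
    if covariates is None:
        Z = np.ones((n, 1))
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        if covariates.shape[0] != n:
            raise ParameterError("covariate rows do not match Y length")
        Z = np.column_stack([np.ones(n), covariates])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ParameterError("perfectly collinear covariates")
    return Y, Z


def fit_null_model(Y, covariates=None,
                   trait_type: str = "continuous") -> NullModel:
    """Fit the covariate-only null model.

    Continuous traits: ordinary least squares of Y on [1, Z].  Dichotomous
    traits (Y in {0,1}, both classes required): logistic regression via
    iteratively reweighted least squares.
    """
    if trait_type not in ("continuous", "dichotomous"):
        raise ParameterError(f"unknown trait_type {trait_type!r}")
    Y, Z = _design(Y, covariates)
    n, q = Z.shape
    if n < 10:
        raise ParameterError("need at least 10 samples")
    if trait_type == "continuous":
        alpha, *_ = np.linalg.lstsq(Z, Y, rcond=None)
        fitted = Z @ alpha
        resid = Y - fitted
        dof = max(n - q, 1)
        sigma2 = float(resid @ resid) / dof
        return NullModel("continuous", alpha, fitted, resid, sigma2, Z)
    values = np.unique(Y)
    if not np.isin(values, (0.0, 1.0)).all():
        raise ParameterError("dichotomous trait must be coded 0/1")
    if values.size < 2:
        raise DegenerateDataError("dichotomous trait has a single class")
    if q == 1:
        mu = np.full(n, Y.mean())
        alpha = np.array([np.log(Y.mean() / (1.0 - Y.mean()))])
    else:
        fit = sm.GLM(Y, Z, family=sm.families.Binomial()).fit()
        alpha = np.asarray(fit.params)
        mu = np.asarray(fit.fittedvalues)
    mu = np.clip(mu, 1e-10, 1.0 - 1e-10)
    return NullModel("dichotomous", alpha, mu, Y - mu, mu * (1.0 - mu), Z)


def score_statistic(null_model: NullModel, kernel, Y=None) -> float:
    """Q = r' K r with r the null residuals (Y - Yhat).

    ``kernel`` may be a KernelMatrix, a raw n x n array, or a feature
    matrix A with K = A A' (recognized by being non-square or explicitly
    shaped n x m).
    """
    r = null_model.residuals
    if isinstance(kernel, KernelMatrix):
        K = kernel.K
        if K.shape[0] != r.size:
            raise ParameterError("kernel dimension does not match samples")
        return float(r @ K @ r)
    arr = np.asarray(kernel, dtype=float)
    if arr.shape[0] != r.size:
        raise ParameterError("kernel dimension does not match samples")
    if arr.ndim == 2 and arr.shape[0] == arr.shape[1]:
        return float(r @ arr @ r)
    v = arr.T @ r
    return float(v @ v)


def _feature_mixture(null_model: NullModel, A: np.ndarray) -> np.ndarray:
    """Eigenvalues of P^(1/2) K P^(1/2) via the m x m matrix A' P A."""
    Z = null_model.design
    if null_model.trait_type == "continuous":
        # P = sigma^2 (I - H); (I - H) is idempotent
        coef, *_ = np.linalg.lstsq(Z, A, rcond=None)
        B = A - Z @ coef
        M = null_model.dispersion * (B.T @ B)
    else:
        V = null_model.dispersion  # per-sample mu(1-mu)
        VA = A * V[:, None]
        VZ = Z * V[:, None]
        ZtVZ = Z.T @ VZ
        PA = VA - VZ @ np.linalg.solve(ZtVZ, VZ.T @ A)
        M = A.T @ PA
    M = 0.5 * (M + M.T)
    return np.linalg.eigvalsh(M)


def null_mixture_weights(null_model: NullModel, kernel) -> np.ndarray:
    """Mixture-of-chi-square weights of Q under the null.

    Continuous: eigenvalues of sigma^2 (I-H) K (I-H); dichotomous:
    eigenvalues of P^(1/2) K P^(1/2) with P = V - VZ(Z'VZ)^-1 Z'V.
    Eigenvalues below ``1e-10 * max`` are dropped.
    """
    arr = kernel.K if isinstance(kernel, KernelMatrix) else \
        np.asarray(kernel, dtype=float)
    n = null_model.n
    is_kernel = (arr.ndim == 2 and arr.shape == (n, n)
                 and np.allclose(arr, arr.T, atol=1e-10))
    if is_kernel:
        Z = null_model.design
        if null_model.trait_type == "continuous":
            coef, *_ = np.linalg.lstsq(Z, arr, rcond=None)
            PK = arr - Z @ coef          # (I-H) K
            coef2, *_ = np.linalg.lstsq(Z, PK.T, rcond=None)
            M = null_model.dispersion * (PK.T - Z @ coef2).T
            lam = np.linalg.eigvalsh(0.5 * (M + M.T))
        else:
            V = null_model.dispersion
            VZ = Z * V[:, None]
            P = np.diag(V) - VZ @ np.linalg.solve(Z.T @ VZ, VZ.T)
            evals, evecs = np.linalg.eigh(0.5 * (P + P.T))
            evals = np.clip(evals, 0.0, None)
            S = evecs * np.sqrt(evals) @ evecs.T
            lam = np.linalg.eigvalsh(S @ arr @ S)
    else:
        lam = _feature_mixture(null_model, arr)
    cutoff = EIGEN_RTOL * max(float(lam.max()), 0.0)
    lam = lam[lam > cutoff]
    if lam.size == 0:
        raise DegenerateDataError("kernel is degenerate under the null")
    return np.sort(lam)[::-1]


def recwas_test(dataset, weights, Y, covariates=None,
                kernel_name: str = "weighted_linear",
                trait_type: str = "continuous", maf_min: float = 0.05,
                peak_id: str = "", weight_power: int = 2,
                pvalue_method: str = "davies",
                davies_acc: float = 1e-9) -> AssociationResult:
    """Random-effect association test of one peak region.

    ``dataset`` is a GenotypeDataset (or a raw n x p dosage matrix, in
    which case the MAF filter is computed from the matrix and ``weights``
    may be a plain array).  Variants are restricted to common SNPs
    (MAF >= ``maf_min``); ``weight_power`` selects the exponent of the
    trained weights in the kernel's diagonal matrix (2, the default, uses
    diag{w_k^2}; 4 squares the weights first).
    """
    if weight_power not in (2, 4):
        raise ParameterError("weight_power must be 2 or 4")
    if isinstance(dataset, GenotypeDataset):
        ids = dataset.variant_ids
        G = dataset.matrix
    else:
        G = np.asarray(dataset, dtype=float)
        ids = [f"snp{j + 1}" for j in range(G.shape[1])]
    if isinstance(weights, WeightVector):
        table = dict(zip(weights.variant_ids, weights.weights))
        w = np.array([table.get(v, 0.0) for v in ids])
    elif weights is None:
        w = None
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.size != len(ids):
            raise ParameterError("weight length does not match SNP count")

    # common-variant filter
    mafs = np.array([compute_maf(G[:, j]) for j in range(G.shape[1])])
    keep = mafs >= maf_min
    if not keep.any():
        return AssociationResult(peak_id, "recwas", kernel_name, np.nan,
                                 np.nan, 0, testable=False,
                                 note="no common variants after MAF filter")
    G = G[:, keep]
    if w is not None:
        w = w[keep]
        if weight_power == 4:
            w = w ** 2
        if kernel_name in ("weighted_linear", "weighted_quadratic", "2wayIX",
                           "weighted_IBS") and not np.any(w != 0.0):
            return AssociationResult(peak_id, "recwas", kernel_name, np.nan,
                                     np.nan, int(keep.sum()), testable=False,
                                     note="all-zero weights (empty model)")

    null = fit_null_model(Y, covariates, trait_type)
    try:
        A = kernel_features(G, w, kernel_name)
        Q = score_statistic(null, A)
        lam = null_mixture_weights(null, A)
    except ParameterError:
        K = build_kernel(G, w, kernel_name)
        Q = score_statistic(null, K)
        lam = null_mixture_weights(null, K)
    p, used = pvalue_mixture_chisq(Q, lam, method=pvalue_method,
                                   acc=davies_acc)
    return AssociationResult(peak_id, "recwas", kernel_name, Q, p,
                             int(keep.sum()), pvalue_method=used)
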