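"""Baseline fixed-effect peak-trait association.

Two routes, as in predicted-expression association frameworks:

* individual-level — impute peak activity as the weighted sum of
  standardized genotypes, then test the trait on the imputed activity with
  a single-df slope test (t for continuous traits, Wald z from logistic
  regression for dichotomous ones).  This is the form used throughout the
  simulation experiments.
* summary-statistic — combine SNP-trait Z scores through the trained
  weights, z_peak = w'z / sqrt(w' S w) with S the SNP LD matrix, for
  workflows that only have GWAS summary statistics.
"""

from __future__ import annotations

import warnings

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .exceptions import DegenerateDataError, ParameterError
from .genio import GenotypeDataset, WeightVector
from .score_test import AssociationResult
from ._utils import standardize_columns

__all__ = ["predict_cistrome", "cwas_individual_test", "cwas_summary_test",
           "reference_ld", "AR_BONFERRONI_N", "H3K27AC_BONFERRONI_N"]

#: number of peaks behind the conventional study-wide thresholds
AR_BONFERRONI_N = 5580
H3K27AC_BONFERRONI_N = 17199

P_FLOOR = 1e-300


def predict_cistrome(G, weights) -> np.ndarray:
    """Imputed peak activity: standardized genotypes times trained weights.

    Variants are aligned by identifier when both sides carry ids; weights
    for SNPs absent from the genotypes are ignored, genotyped SNPs without
    a weight contribute zero.
    """
    if isinstance(G, GenotypeDataset):
        X = G.standardized()
        ids = G.variant_ids
    else:
        X = standardize_columns(np.asarray(G, dtype=float))
        ids = None
    if isinstance(weights, WeightVector):
        if ids is None:
            if len(weights.variant_ids) != X.shape[1]:
                raise ParameterError("weight length does not match SNPs")
            w = weights.weights
        else:
            table = dict(zip(weights.variant_ids, weights.weights))
            if not set(table) & set(ids):
                raise DegenerateDataError(
                    "no overlap between weight and genotype variants")
            w = np.array([table.get(v, 0.0) for v in ids])
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.size != X.shape[1]:
            raise ParameterError("weight length does not match SNPs")
    return X @ w


def cwas_individual_test(c_hat, Y, covariates=None,
                         trait_type: str = "continuous",
                         peak_id: str = "",
                         n_snps: int | None = None) -> AssociationResult:
    """Single-df test of the trait on imputed peak activity.

    Covariates are absorbed into the regression.  A constant imputed
    activity cannot be tested and raises, so callers can report the peak
    untestable instead of faking p = 1.
    """
    c_hat = np.asarray(c_hat, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float).ravel()
    n = Y.size
    if c_hat.size != n:
        raise ParameterError("imputed activity length does not match trait")
    if n < 10:
        raise ParameterError("need at least 10 samples")
    if np.var(c_hat) == 0.0:
        raise DegenerateDataError("constant imputed activity")
    if covariates is None:
        Z = np.ones((n, 1))
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        Z = np.column_stack([np.ones(n), cov])
    X = np.column_stack([Z, c_hat])

    if trait_type == "continuous":
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ coef
        dof = n - X.shape[1]
        rss = float(resid @ resid)
        xtx_inv = np.linalg.inv(X.T @ X)
        if rss <= 1e-12 * float(Y @ Y) or dof < 1:
            # perfect fit: statistic diverges, p numerically zero
            return AssociationResult(peak_id, "cwas", "linear-fixed",
                                     np.inf, P_FLOOR,
                                     n_snps if n_snps is not None else -1)
        se = np.sqrt(rss / dof * xtx_inv[-1, -1])
        tstat = coef[-1] / se
        p = float(2.0 * stats.t.sf(abs(tstat), dof))
        stat = float(tstat)
    elif trait_type == "dichotomous":
        values = np.unique(Y)
        if not np.isin(values, (0.0, 1.0)).all() or values.size < 2:
            raise ParameterError("dichotomous trait must be 0/1, two classes")
        fit = sm.GLM(Y, X, family=sm.families.Binomial()).fit()
        stat = float(fit.params[-1] / fit.bse[-1])
        p = float(2.0 * stats.norm.sf(abs(stat)))
    else:
        raise ParameterError(f"unknown trait_type {trait_type!r}")
    return AssociationResult(peak_id, "cwas", "linear-fixed", stat,
                             max(p, P_FLOOR),
                             n_snps if n_snps is not None else -1)


def reference_ld(G) -> np.ndarray:
    """SNP-SNP correlation matrix from a reference genotype panel.

    Used as the LD input of the summary test when the study's own LD is
    not supplied; constant SNPs get zero off-diagonal correlation and a
    unit diagonal.
    """
    X = standardize_columns(np.asarray(
        G.matrix if isinstance(G, GenotypeDataset) else G, dtype=float))
    S = X.T @ X / X.shape[0]
    np.fill_diagonal(S, 1.0)
    return S


def cwas_summary_test(weights, z_snp, ld_matrix,
                      peak_id: str = "") -> AssociationResult:
    """Summary-statistic combination z_peak = w'z / sqrt(w' S w).

    A near-singular denominator (e.g. perfect LD with cancelling weights)
    is regularized by S <- (S + 0.1 I) / 1.1, which keeps the unit
    diagonal; the result is flagged with a warning.
    """
    w = weights.weights if isinstance(weights, WeightVector) else \
        np.asarray(weights, dtype=float).ravel()
    z = np.asarray(z_snp, dtype=float).ravel()
    S = np.asarray(ld_matrix, dtype=float)
    p_snps = w.size
    if z.size != p_snps or S.shape != (p_snps, p_snps):
        raise ParameterError("w, z and LD dimensions disagree")
    if not np.allclose(S, S.T, atol=1e-8) or \
            not np.allclose(np.diag(S), 1.0, atol=1e-6):
        raise ParameterError("LD matrix must be symmetric with unit diagonal")
    if not np.any(w != 0.0):
        raise DegenerateDataError("all-zero weights")
    denom = float(w @ S @ w)
    if denom <= 1e-10 * float(w @ w):
        warnings.warn("near-singular LD combination; regularizing",
                      RuntimeWarning, stacklevel=2)
        S = (S + 0.1 * np.eye(p_snps)) / 1.1
        denom = float(w @ S @ w)
        if denom <= 0.0:
            raise FloatingPointError(
                "non-positive variance after regularization")
    zpeak = float(w @ z) / np.sqrt(denom)
    p = float(2.0 * stats.norm.sf(abs(zpeak)))
    return AssociationResult(peak_id, "cwas", "summary-z", zpeak,
                             max(p, P_FLOOR), p_snps)
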