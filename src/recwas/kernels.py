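"""Genotype similarity kernels for the variance-component score test.

Every kernel here admits an exact finite feature map ``A`` with
``K = A @ A.T`` as long as dosages are integer {0, 1, 2} (always true for
the IBS family) — the linear family is a weighted genotype matrix, the
polynomial family expands into monomials, and the 3x3 single-SNP IBS
similarity matrix is positive definite so its Cholesky factor provides a
3-dimensional per-SNP embedding.  The score test exploits this: with
``m = A.shape[1]`` features, the null eigenvalues come from an m x m matrix
instead of the n x n kernel, which makes testing thousands of peaks cheap.

Kernel menu (w = per-SNP weights, z = w * G on the appropriate scale):

linear              K_ij = sum_k G_ik G_jk                (standardized G)
weighted_linear     K_ij = sum_k w_k^2 G_ik G_jk          (standardized G)
weighted_quadratic  K_ij = (1 + sum_k w_k^2 G_ik G_jk)^2  (standardized G)
2wayIX              K_ij = 1 + sum_k z_ik z_jk
                         + sum_{k<l} z_ik z_il z_jk z_jl  (standardized G)
IBS                 K_ij = sum_k (2 - |G_ik - G_jk|)      (raw counts)
weighted_IBS        K_ij = sum_k w_k^2 (2 - |G_ik - G_jk|)

``weighted_linear`` is the default kernel of the random-effect test: the
diagonal weight matrix diag{w_1^2, ..., w_p^2} holds squared effect sizes
estimated in the training phase, in place of the MAF-density weights of the
classical sequence kernel association test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateDataError, ParameterError
from ._utils import impute_column_mean, standardize_columns

__all__ = ["KERNEL_NAMES", "KernelMatrix", "kernel_features", "build_kernel",
           "beta_maf_weights"]

KERNEL_NAMES = ("linear", "weighted_linear", "weighted_quadratic", "2wayIX",
                "IBS", "weighted_IBS")

_WEIGHTED = ("weighted_linear", "weighted_quadratic", "2wayIX",
             "weighted_IBS")

# single-SNP IBS similarity between dosages a, b in {0,1,2}: 2 - |a-b|
_IBS_M = np.array([[2.0, 1.0, 0.0],
                   [1.0, 2.0, 1.0],
                   [0.0, 1.0, 2.0]])
_IBS_CHOL = np.linalg.cholesky(_IBS_M)  # rows index the dosage


def beta_maf_weights(mafs, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Classical MAF-density kernel weights, Beta(a, b) evaluated at MAF.

    Effect-size weights from training are the default here; these density
    weights are provided as an option for the otherwise-unweighted kernels
    (pass the result as ``w`` to any weighted kernel).
    """
    from scipy.stats import beta as beta_dist
    mafs = np.asarray(mafs, dtype=float)
    if np.any((mafs < 0) | (mafs > 0.5)):
        raise ParameterError("MAF values must lie in [0, 0.5]")
    return beta_dist.pdf(mafs, a, b)


@dataclass
class KernelMatrix:
    """n x n similarity matrix with its construction tag."""
    K: np.ndarray
    kernel_name: str

    def __post_init__(self):
        if self.K.shape[0] != self.K.shape[1]:
            raise ValueError("kernel must be square")


def _check_weights(w, p, kernel_name):
    if kernel_name in _WEIGHTED:
        if w is None:
            raise ParameterError(f"{kernel_name} kernel requires weights")
        w = np.asarray(w, dtype=float).ravel()
        if w.size != p:
            raise ParameterError("weight length does not match SNP count")
        if not np.all(np.isfinite(w)):
            raise ParameterError("non-finite weights")
        if not np.any(w != 0.0):
            raise DegenerateDataError(
                "all-zero weights: empty model for a weighted kernel")
        return w
    return np.ones(p)


def kernel_features(G: np.ndarray, w=None,
                    kernel_name: str = "weighted_linear",
                    standardize: bool = True) -> np.ndarray:
    """Feature matrix A with ``K = A @ A.T`` (exact, not an approximation).

    Linear/polynomial kernels standardize the genotype columns exactly as
    the weight-training code does; IBS kernels use raw allele counts and
    require integer dosages (mean-imputed fractional dosages have no finite
    IBS embedding — use :func:`build_kernel` for those).
    """
    if kernel_name not in KERNEL_NAMES:
        raise ParameterError(f"unknown kernel {kernel_name!r}")
    G = np.asarray(G, dtype=float)
    n, p = G.shape
    w = _check_weights(w, p, kernel_name)

    def _scaled():
        return standardize_columns(G) if standardize \
            else impute_column_mean(G)

    if kernel_name in ("linear", "weighted_linear"):
        return _scaled() * w

    if kernel_name in ("weighted_quadratic", "2wayIX"):
        z = _scaled() * w
        ones = np.ones((n, 1))
        cross_cols = []
        for k in range(p):
            for l in range(k + 1, p):
                cross_cols.append(z[:, k] * z[:, l])
        cross = (np.column_stack(cross_cols) if cross_cols
                 else np.empty((n, 0)))
        if kernel_name == "2wayIX":
            # 1 + <z, z'> + sum_{k<l} (z_k z_l)(z'_k z'_l)
            return np.hstack([ones, z, cross])
        # (1 + <z, z'>)^2 = 1 + 2<z,z'> + <z,z'>^2, expanded to monomials
        return np.hstack([ones, np.sqrt(2.0) * z, z * z,
                          np.sqrt(2.0) * cross])

    # IBS family on raw counts
    Gi = impute_column_mean(G)
    if not np.isin(Gi, (0.0, 1.0, 2.0)).all():
        raise ParameterError(
            "IBS feature map requires integer dosages {0,1,2}")
    idx = Gi.astype(int)
    A = _IBS_CHOL[idx]                      # (n, p, 3)
    if kernel_name == "weighted_IBS":
        A = A * np.abs(w)[None, :, None]
    return A.reshape(n, 3 * p)


def build_kernel(G: np.ndarray, w=None,
                 kernel_name: str = "weighted_linear",
                 standardize: bool = True) -> KernelMatrix:
    """Materialize the n x n kernel matrix (symmetric, PSD)."""
    G = np.asarray(G, dtype=float)
    n, p = G.shape
    try:
        A = kernel_features(G, w, kernel_name, standardize=standardize)
        K = A @ A.T
    except ParameterError:
        if kernel_name not in ("IBS", "weighted_IBS"):
            raise
        # fractional dosages: direct pairwise IBS
        w_arr = _check_weights(w, p, kernel_name)
        w2 = w_arr ** 2 if kernel_name == "weighted_IBS" else np.ones(p)
        Gi = impute_column_mean(G)
        K = np.zeros((n, n))
        for k in range(p):
            K += w2[k] * (2.0 - np.abs(Gi[:, k, None] - Gi[None, :, k]))
    K = 0.5 * (K + K.T)
    return KernelMatrix(K=K, kernel_name=kernel_name)
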