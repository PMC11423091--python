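"""Internal numeric helpers: column standardization and mean imputation."""

from __future__ import annotations

import numpy as np


def impute_column_mean(matrix: np.ndarray) -> np.ndarray:
    """Replace missing genotype calls (NaN) by their column mean.

    Used only at test/prediction time; frequency computations always work
    on the raw calls.
    """
    out = np.array(matrix, dtype=float, copy=True)
    if not np.isnan(out).any():
        return out
    means = np.nanmean(out, axis=0)
    means = np.where(np.isnan(means), 0.0, means)  # all-missing column
    idx = np.where(np.isnan(out))
    out[idx] = means[idx[1]]
    return out


def standardize_columns(matrix: np.ndarray) -> np.ndarray:
    """Center and scale columns to mean 0, variance 1 (population variance).

    Constant columns are mapped to all-zero columns rather than NaN so a
    monomorphic SNP simply drops out of any weighted combination.
    """
    x = impute_column_mean(matrix)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    out = (x - mu) / sd_safe
    out[:, sd == 0] = 0.0
    return out
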