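"""Log2 transform and quantile normalization.

Quantile normalization forces every sample (or, in gene mode, every protein)
to share one reference distribution: the i-th smallest value in each column is
replaced by the across-column mean (or median) of i-th smallest values, with
tied values receiving the mean reference value of their tied ranks. The
default axis is sample-wise — the classical procedure that makes intensities
comparable across samples before testing; the row-wise variant is provided
because depletion-screen workflows sometimes describe the normalization as
"gene-based".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import StateError, ValidationError
from .io import LINEAR, LOG2, AbundanceMatrix

MODES = ("sample_quantile", "gene_quantile")
REFERENCES = ("mean_of_sorted", "median_of_sorted")


@dataclass
class NormalizationConfig:
    mode: str = "sample_quantile"
    reference: str = "mean_of_sorted"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.reference not in REFERENCES:
            raise ValidationError(
                f"reference must be one of {REFERENCES}, got {self.reference!r}"
            )


def log2_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Switch a linear matrix to log2 scale; missing cells stay missing."""
    if matrix.scale == LOG2:
        raise StateError("matrix is already log2-scaled")
    X = matrix.values.to_numpy()
    bad = np.argwhere(~np.isnan(X) & (X <= 0))
    if bad.size:
        i, j = bad[0]
        raise ValidationError(
            f"non-positive intensity at protein {matrix.protein_ids[i]!r}, "
            f"sample {matrix.sample_ids[j]!r}"
        )
    out = matrix.values.copy()
    out.iloc[:, :] = np.log2(X)
    return AbundanceMatrix(out, LOG2)


def linear_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Inverse of log2_transform (2**x); used when writing linear fixtures."""
    if matrix.scale == LINEAR:
        raise StateError("matrix is already linear-scaled")
    out = matrix.values.copy()
    out.iloc[:, :] = np.exp2(matrix.values.to_numpy())
    return AbundanceMatrix(out, LINEAR)


def _quantile_normalize_columns(X: np.ndarray, reference: str) -> np.ndarray:
    """Classical column quantile normalization with tied-rank averaging."""
    sorted_cols = np.sort(X, axis=0)
    if reference == "mean_of_sorted":
        ref = sorted_cols.mean(axis=1)
    else:
        ref = np.median(sorted_cols, axis=1)
    out = np.empty_like(X)
    n = X.shape[0]
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = ref.copy()
        # average the reference over runs of tied values
        sorted_vals = col[order]
        start = 0
        while start < n:
            stop = start + 1
            while stop < n and sorted_vals[stop] == sorted_vals[start]:
                stop += 1
            if stop - start > 1:
                assigned[start:stop] = ref[start:stop].mean()
            start = stop
        out[order, j] = assigned
    return out


def quantile_normalize(
    matrix: AbundanceMatrix, config: NormalizationConfig | None = None
) -> AbundanceMatrix:
    """Quantile-normalize a complete log2 matrix along the configured axis."""
    config = config or NormalizationConfig()
    matrix.require_scale(LOG2, "quantile_normalize")
    if matrix.n_missing:
        raise StateError("matrix has missing cells; impute before normalizing")
    X = matrix.values.to_numpy()
    if config.mode == "sample_quantile":
        normalized = _quantile_normalize_columns(X, config.reference)
    else:
        normalized = _quantile_normalize_columns(X.T, config.reference).T
    out = matrix.values.copy()
    out.iloc[:, :] = normalized
    return AbundanceMatrix(out, LOG2)
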