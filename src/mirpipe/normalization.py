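"""log2 transform and between-array normalization (quantile and scale).

Quantile normalization is the classic rank-mean algorithm: sort each array's
values, average across arrays at each rank, and hand every value the mean of
its rank; ties within an array receive the mean of the quantile values their
tied ranks span.  Afterwards every array has the identical distribution.

Scale normalization equalizes a per-array scale statistic: each array is
multiplied by (geometric mean of all array medians) / (its own median), so the
medians of all arrays end up at the geometric mean of the original medians.
An additive variant (median-centering in log2 space) is available for users
who prefer shifting over scaling on the log scale.

Both operations are also exposed as scikit-learn transformers operating on
``X`` of shape ``(n_arrays, n_probes)`` (arrays as samples), composing with
sklearn pipelines; the ExpressionMatrix functions are the domain-facing
surface (probes × arrays).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import ValidationError
from .qc import ExpressionMatrix


# ---------------------------------------------------------------------------
# core numerics (columns = arrays)
# ---------------------------------------------------------------------------

def _quantile_normalize_columns(X: np.ndarray) -> np.ndarray:
    """Rank-mean quantile normalization over columns of a 2-D array."""
    if X.size == 0:
        raise ValidationError("cannot quantile-normalize an empty matrix")
    n, m = X.shape
    ref = np.sort(X, axis=0).mean(axis=1)  # quantile means by rank
    out = np.empty_like(X, dtype=float)
    for j in range(m):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n, dtype=float)
        assigned[order] = ref
        # ties: average the quantile values the tied ranks span
        s = pd.Series(assigned)
        out[:, j] = s.groupby(pd.Series(col)).transform("mean").to_numpy()
    return out


def _scale_normalize_columns(X: np.ndarray, mode: str = "multiplicative") -> np.ndarray:
    if X.size == 0:
        raise ValidationError("cannot scale-normalize an empty matrix")
    med = np.median(X, axis=0)
    if mode == "multiplicative":
        if np.any(med <= 0):
            raise ValidationError(
                "scale normalization needs positive column medians; "
                "raise the log2 floor so medians stay positive"
            )
        target = np.exp(np.mean(np.log(med)))
        return X * (target / med)
    if mode == "additive":
        return X - med + med.mean()
    raise ValidationError(f"unknown scale mode '{mode}'")


# ---------------------------------------------------------------------------
# ExpressionMatrix surface
# ---------------------------------------------------------------------------

def log2_transform(m: ExpressionMatrix, floor: float = 1.0) -> ExpressionMatrix:
    """log2 with flooring: value -> log2(max(value, floor)).

    Background-subtracted signals can be ≤ 0; the floor (default 1
    fluorescence unit) keeps the log defined.
    """
    if floor <= 0:
        raise ValidationError("log2 floor must be > 0")
    if m.stage != "raw_averaged":
        raise ValidationError(f"log2_transform expects stage raw_averaged, got {m.stage}")
    values = np.log2(m.values.clip(lower=floor))
    return ExpressionMatrix(values, m.detection_counts, stage="log2")


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Between-array quantile normalization of a log2 matrix."""
    if m.stage != "log2":
        raise ValidationError(f"quantile_normalize expects stage log2, got {m.stage}")
    out = _quantile_normalize_columns(m.values.to_numpy(dtype=float))
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values, m.detection_counts, stage="normalized")


def scale_normalize(m: ExpressionMatrix, mode: str = "multiplicative") -> ExpressionMatrix:
    """Between-array scale normalization (median-ratio) of a log2 matrix."""
    if m.stage != "log2":
        raise ValidationError(f"scale_normalize expects stage log2, got {m.stage}")
    out = _scale_normalize_columns(m.values.to_numpy(dtype=float), mode)
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values, m.detection_counts, stage="normalized")


# ---------------------------------------------------------------------------
# sklearn transformers (rows = arrays)
# ---------------------------------------------------------------------------

class Log2Floor(TransformerMixin, BaseEstimator):
    """Floored log2 transform, ``log2(max(x, floor))``, as a transformer."""

    def __init__(self, floor: float = 1.0):
        self.floor = floor

    def fit(self, X, y=None):
        if self.floor <= 0:
            raise ValidationError("log2 floor must be > 0")
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return np.log2(np.maximum(X, self.floor))


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Quantile normalization across arrays (rows of ``X``).

    ``fit`` learns the reference distribution (mean of sorted rows);
    ``transform`` maps each row onto it by rank with tie averaging.
    ``fit_transform`` on one batch is the classic between-array algorithm.
    """

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        self.reference_distribution_ = np.sort(X, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError("feature count differs from fit")
        return _quantile_normalize_with_reference(X, self.reference_distribution_)


def _quantile_normalize_with_reference(X: np.ndarray, ref: np.ndarray) -> np.ndarray:
    out = np.empty_like(X, dtype=float)
    n = X.shape[1]
    for i in range(X.shape[0]):
        row = X[i]
        order = np.argsort(row, kind="stable")
        assigned = np.empty(n, dtype=float)
        assigned[order] = ref
        s = pd.Series(assigned)
        out[i] = s.groupby(pd.Series(row)).transform("mean").to_numpy()
    return out


class ScaleNormalizer(TransformerMixin, BaseEstimator):
    """Median-ratio scale normalization across arrays (rows of ``X``)."""

    def __init__(self, mode: str = "multiplicative"):
        self.mode = mode

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        med = np.median(X, axis=1)
        if self.mode == "multiplicative":
            if np.any(med <= 0):
                raise ValidationError("scale normalization needs positive medians")
            self.target_median_ = float(np.exp(np.mean(np.log(med))))
        elif self.mode == "additive":
            self.target_median_ = float(med.mean())
        else:
            raise ValidationError(f"unknown scale mode '{self.mode}'")
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        med = np.median(X, axis=1, keepdims=True)
        if self.mode == "multiplicative":
            if np.any(med <= 0):
                raise ValidationError("scale normalization needs positive medians")
            return X * (self.target_median_ / med)
        return X - med + self.target_median_
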