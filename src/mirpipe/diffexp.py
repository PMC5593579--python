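"""Welch two-sample differential expression between ALK+ and ALK− groups.

For every probe the unpaired, two-tailed, unequal-variance t-test (Welch) is
applied to the normalized log2 values of the two groups:

    t  = (x̄ − ȳ) / sqrt(s²x/nx + s²y/ny)
    df = (s²x/nx + s²y/ny)² / [ (s²x/nx)²/(nx−1) + (s²y/ny)²/(ny−1) ]

with the two-sided p from the central t distribution (df not rounded).
Selection is on raw p < alpha, matching the study's design; Benjamini–
Hochberg q-values are reported per record for transparency but never used to
select.  The fold change is 2^|Δ(log2 means)| with a direction call naming
the lower group (``down_in_alk_pos`` when the ALK− mean is higher).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.multiclass import unique_labels
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .qc import ExpressionMatrix

DOWN_IN_ALK_POS = "down_in_alk_pos"
UP_IN_ALK_POS = "up_in_alk_pos"
FLAT = "flat"

RECORD_COLUMNS = [
    "probe_name",
    "mean_alk_neg",
    "mean_alk_pos",
    "t_stat",
    "df",
    "p_raw",
    "fold_change",
    "direction",
    "q_bh",
    "significant",
]


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's t statistic, Welch–Satterthwaite df, and two-sided p.

    Both groups need ≥ 2 observations.  If both sample variances are zero the
    convention is t = 0, p = 1 for equal means; unequal means with zero
    variance is degenerate and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("welch_t needs at least 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        raise ValidationError("both groups have zero variance and unequal means")
    se2x, se2y = vx / x.size, vy / y.size
    t = (x.mean() - y.mean()) / np.sqrt(se2x + se2y)
    df = (se2x + se2y) ** 2 / (
        se2x**2 / (x.size - 1) + se2y**2 / (y.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _welch_t_matrix(
    Xa: np.ndarray, Xb: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch test: rows are probes, columns group arrays.

    Probes where both groups have zero variance get p = 1 when the means are
    equal and p = 0 (t = ±inf) when they differ; a run is never aborted for
    one degenerate probe.
    """
    na, nb = Xa.shape[1], Xb.shape[1]
    ma, mb = Xa.mean(axis=1), Xb.mean(axis=1)
    va, vb = Xa.var(axis=1, ddof=1), Xb.var(axis=1, ddof=1)
    se2a, se2b = va / na, vb / nb
    denom = np.sqrt(se2a + se2b)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
        df = (se2a + se2b) ** 2 / (
            se2a**2 / (na - 1) + se2b**2 / (nb - 1)
        )
    degen = denom == 0
    equal = degen & (ma == mb)
    differ = degen & (ma != mb)
    t = np.where(equal, 0.0, t)
    t = np.where(differ, np.where(ma > mb, np.inf, -np.inf), t)
    df = np.where(degen, na + nb - 2, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(equal, 1.0, p)
    p = np.where(differ, 0.0, p)
    return t, df, p


def fold_change(mean_a: float, mean_b: float) -> tuple[float, str]:
    """Fold change and direction from two log2 group means.

    ``mean_a`` is the ALK− group mean, ``mean_b`` the ALK+ group mean:
    fc = 2^|mean_a − mean_b|; direction is ``down_in_alk_pos`` when the ALK−
    mean is higher, ``up_in_alk_pos`` when lower, ``flat`` when equal.
    """
    if not (np.isfinite(mean_a) and np.isfinite(mean_b)):
        raise ValidationError("fold_change needs finite log2 means")
    fc = float(2.0 ** abs(mean_a - mean_b))
    if mean_a > mean_b:
        return fc, DOWN_IN_ALK_POS
    if mean_a < mean_b:
        return fc, UP_IN_ALK_POS
    return fc, FLAT


@dataclass
class DiffExpTable:
    """Per-probe Welch results, sorted by raw p (probe-name tiebreak)."""

    records: pd.DataFrame
    alpha: float

    @property
    def n_tested(self) -> int:
        return len(self.records)

    @property
    def n_significant(self) -> int:
        return int(self.records["significant"].sum())

    @property
    def n_down_in_alk_pos(self) -> int:
        sig = self.records[self.records["significant"]]
        return int((sig["direction"] == DOWN_IN_ALK_POS).sum())

    def significant_records(self) -> pd.DataFrame:
        return self.records[self.records["significant"]].reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


class WelchDifferentialExpression(BaseEstimator):
    """Per-feature Welch testing as a scikit-learn estimator.

    ``fit(X, y)`` takes ``X`` of shape ``(n_arrays, n_probes)`` and a
    two-class group label vector ``y``.  ``group_order`` names which label is
    the reference (ALK−) group; by default ``("ALK_NEG", "ALK_POS")`` when
    those labels are present, else the sorted labels.

    Fitted attributes: ``results_`` (DataFrame, one row per feature, sorted
    by raw p), ``classes_``, ``n_significant_``, ``n_down_``.
    """

    def __init__(self, alpha: float = 0.05, group_order: tuple[str, str] | None = None):
        self.alpha = alpha
        self.group_order = group_order

    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValidationError("X must be (n_arrays, n_probes) aligned with y")
        labels = list(unique_labels(y))
        if len(labels) != 2:
            raise ValidationError(f"need exactly two groups, got {labels}")
        if self.group_order is not None:
            neg, pos = self.group_order
        elif {"ALK_NEG", "ALK_POS"} <= set(labels):
            neg, pos = "ALK_NEG", "ALK_POS"
        else:
            neg, pos = sorted(labels)
        if set(labels) != {neg, pos}:
            raise ValidationError(f"group_order {self.group_order} does not match labels {labels}")
        Xn = X[y == neg].T  # probes x arrays
        Xp = X[y == pos].T
        if Xn.shape[1] < 2 or Xp.shape[1] < 2:
            raise ValidationError("each group needs at least 2 arrays")
        t, df, p = _welch_t_matrix(Xn, Xp)
        mean_neg = Xn.mean(axis=1)
        mean_pos = Xp.mean(axis=1)
        delta = mean_neg - mean_pos
        fc = 2.0 ** np.abs(delta)
        direction = np.where(delta > 0, DOWN_IN_ALK_POS, np.where(delta < 0, UP_IN_ALK_POS, FLAT))
        q = multipletests(p, method="fdr_bh")[1]
        names = (
            list(feature_names)
            if feature_names is not None
            else [f"feature_{i}" for i in range(X.shape[1])]
        )
        res = pd.DataFrame(
            {
                "probe_name": names,
                "mean_alk_neg": mean_neg,
                "mean_alk_pos": mean_pos,
                "t_stat": t,
                "df": df,
                "p_raw": p,
                "fold_change": fc,
                "direction": direction,
                "q_bh": q,
                "significant": p < self.alpha,
            }
        )
        res = res.sort_values(["p_raw", "probe_name"], kind="stable").reset_index(drop=True)
        self.classes_ = (neg, pos)
        self.results_ = res
        self.n_significant_ = int(res["significant"].sum())
        self.n_down_ = int(
            ((res["direction"] == DOWN_IN_ALK_POS) & res["significant"]).sum()
        )
        return self


def run_diffexp(
    m: ExpressionMatrix,
    design: Mapping[str, str],
    alpha: float = 0.05,
    group_order: tuple[str, str] | None = None,
) -> DiffExpTable:
    """Welch differential expression on a normalized ExpressionMatrix.

    ``design`` maps sample id → group label (two groups, ≥ 2 arrays each).
    """
    missing = [s for s in m.sample_ids if s not in design]
    if missing:
        raise ValidationError(f"samples missing from design: {missing}")
    y = np.array([design[s] for s in m.sample_ids])
    est = WelchDifferentialExpression(alpha=alpha, group_order=group_order)
    est.fit(m.values.to_numpy(dtype=float).T, y, feature_names=m.probe_names)
    return DiffExpTable(records=est.results_, alpha=alpha)
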