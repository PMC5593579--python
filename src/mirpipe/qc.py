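"""Detection-call QC cascade for spotted miRNA arrays.

The cascade, in fixed order:

1. detection calls — a spot is "detected" when it passes a configurable set of
   flag conditions and is an experimental (non-control) feature;
2. probe filter — a probe is dropped when its total number of detected
   replicate spots, summed across all arrays of a group, is below
   ``min_detected`` in either group;
3. array filter — an array is dropped when its detected-spot count falls below
   MEAN − k·SD of the counts across arrays (k = 2 by default);
4. replicate averaging — background-subtracted signals of a probe's duplicate
   spots on each array are averaged into one value per probe per array.

The probe filter is applied before array removal and is not recomputed
afterwards.  Averaging uses all replicate spots, detected or not, so the
resulting matrix has no missing values; detection counts are carried alongside
for bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataIntegrityError, ValidationError
from .fe_io import ArrayScan

HSA_PREFIX = "hsa"


@dataclass(frozen=True)
class DetectionPolicy:
    """Pure predicate deciding whether a spot counts as detected.

    ``require_true`` flags must all be true, ``require_false`` flags must all
    be false, and the spot must be an experimental feature
    (``control_type == 0``).  The default encodes standard FE detection
    semantics: well above background and not saturated, not a feature
    non-uniformity or population outlier, not manually flagged.
    """

    require_true: tuple[str, ...] = ("well_above_background",)
    require_false: tuple[str, ...] = (
        "saturated",
        "nonuniform_outlier",
        "population_outlier",
        "manual_flag",
    )

    @property
    def required_flags(self) -> tuple[str, ...]:
        return tuple(self.require_true) + tuple(self.require_false)


DEFAULT_POLICY = DetectionPolicy()


def call_detected(scan: ArrayScan, policy: DetectionPolicy = DEFAULT_POLICY) -> np.ndarray:
    """Boolean detection vector aligned with ``scan.frame`` rows.

    Control spots (``control_type != 0``) are never detected.  Raises
    :class:`ConfigurationError` if the policy references a flag the scan does
    not carry.
    """
    present = set(scan.flag_names)
    for flag in policy.required_flags:
        if flag not in present:
            raise ConfigurationError(
                f"detection policy requires flag '{flag}' absent from array "
                f"'{scan.sample_id}'"
            )
    det = scan.frame["control_type"].to_numpy() == 0
    for flag in policy.require_true:
        det &= scan.frame[flag].to_numpy()
    for flag in policy.require_false:
        det &= ~scan.frame[flag].to_numpy()
    return det


def count_detected_per_array(
    scans: Sequence[ArrayScan],
    policy: DetectionPolicy = DEFAULT_POLICY,
    prefix: str = HSA_PREFIX,
) -> dict[str, int]:
    """Detected-spot count per array, over ``prefix`` (human miRNA) spots only."""
    if not scans:
        raise ValidationError("no arrays given")
    counts: dict[str, int] = {}
    for scan in scans:
        det = call_detected(scan, policy)
        is_hsa = scan.frame["probe_name"].str.startswith(prefix).to_numpy()
        counts[scan.sample_id] = int(np.sum(det & is_hsa))
    return counts


def remove_low_count_arrays(
    counts: Mapping[str, int], sd_multiplier: float = 2.0, ddof: int = 1
) -> tuple[list[str], list[str], float]:
    """MEAN − k·SD array exclusion.

    The threshold is computed once from all arrays' detected-spot counts
    (sample standard deviation by default); arrays strictly below it are
    removed.  Returns ``(kept_ids, removed_ids, threshold)``.
    """
    if len(counts) < 2:
        raise ValidationError("array exclusion needs at least 2 arrays")
    ids = list(counts)
    values = np.array([counts[i] for i in ids], dtype=float)
    threshold = float(values.mean() - sd_multiplier * values.std(ddof=ddof))
    removed = [i for i, v in zip(ids, values) if v < threshold]
    kept = [i for i in ids if i not in removed]
    return kept, removed, threshold


@dataclass
class QcReport:
    """Machine-readable record of what the QC cascade did and why."""

    detected_per_array: dict[str, int] = field(default_factory=dict)
    removed_arrays: list[str] = field(default_factory=list)
    array_threshold: float | None = None
    n_probes_kept: int = 0
    n_probes_removed: int = 0
    parameters: dict = field(default_factory=dict)

    @property
    def n_probes_total(self) -> int:
        return self.n_probes_kept + self.n_probes_removed

    def to_dict(self) -> dict:
        return {
            "detected_per_array": self.detected_per_array,
            "removed_arrays": self.removed_arrays,
            "array_threshold": self.array_threshold,
            "n_probes_kept": self.n_probes_kept,
            "n_probes_removed": self.n_probes_removed,
            "parameters": self.parameters,
        }


def _probe_group_detection(
    scans: Sequence[ArrayScan],
    design: Mapping[str, str],
    policy: DetectionPolicy,
    prefix: str,
) -> tuple[list[str], pd.DataFrame]:
    """Per-probe detected-spot totals by group (replicate spots each count)."""
    pieces = []
    probe_order: list[str] = []
    seen: set[str] = set()
    for scan in scans:
        if scan.sample_id not in design:
            raise ValidationError(f"array '{scan.sample_id}' missing from design")
        det = call_detected(scan, policy)
        mask = scan.frame["probe_name"].str.startswith(prefix).to_numpy()
        sub = pd.DataFrame(
            {
                "probe_name": scan.frame["probe_name"].to_numpy()[mask],
                "detected": det[mask].astype(int),
                "group": design[scan.sample_id],
            }
        )
        pieces.append(sub)
        for p in sub["probe_name"]:
            if p not in seen:
                seen.add(p)
                probe_order.append(p)
    allspots = pd.concat(pieces, ignore_index=True)
    table = (
        allspots.groupby(["probe_name", "group"], sort=False)["detected"]
        .sum()
        .unstack("group", fill_value=0)
    )
    return probe_order, table


def filter_probes_by_group_detection(
    scans: Sequence[ArrayScan],
    design: Mapping[str, str],
    policy: DetectionPolicy = DEFAULT_POLICY,
    min_detected: int = 5,
    prefix: str = HSA_PREFIX,
) -> tuple[list[str], QcReport]:
    """Remove probes with fewer than ``min_detected`` detected spots in a group.

    A probe's per-group count sums detected replicate spots across every array
    of that group; the probe is removed if the count is strictly below
    ``min_detected`` in *either* group.  Returns the kept probe names (input
    order preserved) and a :class:`QcReport` with kept/removed totals.
    """
    groups = sorted(set(design.values()))
    if len(groups) != 2:
        raise ValidationError(f"design must define exactly two groups, got {groups}")
    present = {design[s.sample_id] for s in scans if s.sample_id in design}
    for g in groups:
        if g not in present:
            raise ValidationError(f"group '{g}' has zero arrays")
    probe_order, table = _probe_group_detection(scans, design, policy, prefix)
    ok = (table[groups[0]] >= min_detected) & (table[groups[1]] >= min_detected)
    kept = [p for p in probe_order if ok.get(p, False)]
    report = QcReport(
        n_probes_kept=len(kept),
        n_probes_removed=len(probe_order) - len(kept),
        parameters={"min_detected": min_detected, "prefix": prefix},
    )
    return kept, report


@dataclass
class ExpressionMatrix:
    """Probes × arrays expression values with detection bookkeeping.

    ``values`` is a DataFrame indexed by probe name with one column per
    sample; ``detection_counts`` (same shape) counts the detected replicate
    spots behind each averaged value.  ``stage`` tracks the processing state:
    ``raw_averaged`` → ``log2`` → ``normalized``.
    """

    values: pd.DataFrame
    detection_counts: pd.DataFrame | None = None
    stage: str = "raw_averaged"

    def __post_init__(self):
        if self.stage not in ("raw_averaged", "log2", "normalized"):
            raise ValidationError(f"unknown stage '{self.stage}'")
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        if self.detection_counts is not None:
            if self.detection_counts.shape != self.values.shape:
                raise ValidationError("detection_counts shape mismatch")

    @property
    def probe_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def average_replicates(
    scans: Sequence[ArrayScan],
    kept_probes: Sequence[str],
    policy: DetectionPolicy | None = DEFAULT_POLICY,
) -> ExpressionMatrix:
    """Average duplicate spots' background-subtracted signals per array.

    All replicate spots of a probe enter the mean regardless of detection, so
    the matrix is complete; per-cell detected-replicate counts are recorded in
    ``detection_counts`` (all-replicates if ``policy`` is None).
    """
    kept = list(kept_probes)
    kept_set = set(kept)
    means = {}
    counts = {}
    for scan in scans:
        mask = scan.frame["probe_name"].isin(kept_set).to_numpy()
        sub = scan.frame.loc[mask, ["probe_name", "signal_bgsub"]]
        mean = sub.groupby("probe_name", sort=False)["signal_bgsub"].mean()
        missing = kept_set - set(mean.index)
        if missing:
            raise DataIntegrityError(
                f"probe '{sorted(missing)[0]}' absent from array '{scan.sample_id}'"
            )
        if policy is not None:
            det = call_detected(scan, policy)[mask]
        else:
            det = np.ones(mask.sum(), dtype=bool)
        cnt = (
            pd.DataFrame({"probe_name": sub["probe_name"], "det": det.astype(int)})
            .groupby("probe_name", sort=False)["det"]
            .sum()
        )
        means[scan.sample_id] = mean.reindex(kept)
        counts[scan.sample_id] = cnt.reindex(kept)
    values = pd.DataFrame(means).loc[kept]
    det_counts = pd.DataFrame(counts).loc[kept].astype(int)
    return ExpressionMatrix(values, det_counts, stage="raw_averaged")
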