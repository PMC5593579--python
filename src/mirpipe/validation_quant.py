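"""Downstream quantification arithmetic: ΔCt qPCR, dual-luciferase, MTT.

ΔCt relative quantification
    ΔCt(sample) = Ct(target) − geometric mean of the reference genes' Ct;
    relative level = E^(−ΔCt) with amplification efficiency E = 2 by default;
    levels are rescaled so the least-expressed sample sits at fold 1.

Dual-luciferase chain
    per well: firefly / renilla; per condition: mean ratio; reporter
    conditions divided by the empty-vector mean ratio; everything expressed
    as percent of the negative-control condition (≡ 100 %).

MTT viability
    per well: A595 − A655 (background); per condition: mean signal; percent
    of the negative-control mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class CtTable:
    """Threshold cycles, samples × genes, with target and reference genes."""

    ct: pd.DataFrame
    target: str
    references: tuple[str, ...]

    def __post_init__(self):
        self.references = tuple(self.references)
        if not self.references:
            raise ValidationError("reference gene set must be non-empty")
        if self.target in self.references:
            raise ValidationError("target gene must not be a reference gene")
        for g in (self.target, *self.references):
            if g not in self.ct.columns:
                raise ValidationError(f"gene '{g}' missing from Ct table")
        vals = self.ct[[self.target, *self.references]].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValidationError("all Ct values must be finite and > 0")


def delta_ct(table: CtTable, efficiency: float = 2.0) -> pd.DataFrame:
    """Comparative ΔCt relative expression per sample.

    Returns a DataFrame indexed like the Ct table with columns ``delta_ct``,
    ``relative_level`` (E^−ΔCt) and ``fold_vs_min`` (rescaled so the least
    expressed sample is exactly 1).
    """
    if efficiency <= 1:
        raise ValidationError("amplification efficiency must be > 1")
    refs = table.ct[list(table.references)].to_numpy(dtype=float)
    geo = np.exp(np.mean(np.log(refs), axis=1))
    dct = table.ct[table.target].to_numpy(dtype=float) - geo
    rel = efficiency ** (-dct)
    fold = rel / rel.min()
    return pd.DataFrame(
        {"delta_ct": dct, "relative_level": rel, "fold_vs_min": fold},
        index=table.ct.index,
    )


@dataclass
class PlateReading:
    """Plate-reader wells: condition, replicate, and paired readings.

    ``kind`` is ``"luciferase"`` (columns ``firefly``, ``renilla``) or
    ``"mtt"`` (columns ``a595``, ``a655``).
    """

    wells: pd.DataFrame
    kind: str

    def __post_init__(self):
        if self.kind not in ("luciferase", "mtt"):
            raise ValidationError(f"unknown plate kind '{self.kind}'")
        need = ("firefly", "renilla") if self.kind == "luciferase" else ("a595", "a655")
        for col in ("condition", "replicate", *need):
            if col not in self.wells.columns:
                raise ValidationError(f"plate wells missing column '{col}'")
        dup = self.wells.duplicated(["condition", "replicate"])
        if dup.any():
            raise ValidationError("replicate indices must be unique per condition")


def luciferase_normalize(
    plate: PlateReading,
    empty_vector_condition: str,
    negative_control_condition: str,
) -> dict[str, float]:
    """Firefly/renilla → empty-vector → percent-of-negative-control chain.

    Returns condition → percent activity (the negative control is exactly
    100).  Raises if any renilla count is non-positive, naming the well.
    """
    if plate.kind != "luciferase":
        raise ValidationError("expected a luciferase plate")
    wells = plate.wells
    for cond in (empty_vector_condition, negative_control_condition):
        if cond not in set(wells["condition"]):
            raise ValidationError(f"condition '{cond}' missing from plate")
    bad = wells["renilla"].to_numpy(dtype=float) <= 0
    if bad.any():
        w = wells[bad].iloc[0]
        raise ValidationError(
            f"non-positive renilla in condition '{w['condition']}' "
            f"replicate {w['replicate']}"
        )
    ratio = wells["firefly"].astype(float) / wells["renilla"].astype(float)
    mean_ratio = ratio.groupby(wells["condition"]).mean()
    rel = mean_ratio / mean_ratio[empty_vector_condition]
    percent = 100.0 * rel / rel[negative_control_condition]
    return {c: float(percent[c]) for c in mean_ratio.index}


def mtt_viability(
    plate: PlateReading, negative_control_condition: str
) -> dict[str, float]:
    """Background-subtracted viability as percent of the negative control."""
    if plate.kind != "mtt":
        raise ValidationError("expected an MTT plate")
    wells = plate.wells
    if negative_control_condition not in set(wells["condition"]):
        raise ValidationError(
            f"condition '{negative_control_condition}' missing from plate"
        )
    signal = wells["a595"].astype(float) - wells["a655"].astype(float)
    mean_signal = signal.groupby(wells["condition"]).mean()
    nc = mean_signal[negative_control_condition]
    if nc <= 0:
        raise ValidationError("negative-control mean signal must be > 0")
    return {c: float(100.0 * mean_signal[c] / nc) for c in mean_signal.index}
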