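"""Synthetic data with planted ground truth for every pipeline stage.

The array generator emulates the statistical structure the analysis assumes:
two groups of single-channel arrays carrying a few hundred human ('hsa')
miRNA probes spotted in duplicate plus non-hsa control features; per-spot
log-normal intensities (log2 intensity = probe baseline + group effect for
differentially expressed probes + spot noise); per-spot detection flags that
fail with a configurable miss rate, optionally inflated on deliberately
degraded arrays to exercise the MEAN−2SD array exclusion.  Background
subtraction leaves a small additive residual, so signals can dip below zero
and downstream flooring is exercised.

Defaults mirror the study design being emulated: two replicate spots per
probe, a 10-vs-6 two-group layout (the cell-line screen), 866 human probes
(the array's human miRNA catalogue) of which 30 are planted as down-regulated
in the ALK+ group at a 1.5 log2 effect (≈ 2.8-fold, the middle of the
reported candidate range).

Companion generators produce qPCR Ct tables and luciferase/MTT plates whose
true effects the quantification stage must recover exactly in the noiseless
limit.  One integer seed drives all randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .fe_io import DEFAULT_FLAG_COLUMNS, ArrayScan, SampleSheet
from .validation_quant import CtTable, PlateReading

GROUP_POS = "ALK_POS"
GROUP_NEG = "ALK_NEG"


@dataclass
class SimulationConfig:
    n_probes: int = 866
    replicates_per_probe: int = 2
    n_arrays_per_group: tuple[int, int] = (10, 6)  # (ALK_POS, ALK_NEG)
    n_de_probes: int = 30
    de_log2_effect: float = 1.5  # ALK_NEG minus ALK_POS for planted probes
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 2.0
    noise_log2_sd: float = 0.5
    detection_miss_rate: float = 0.05
    n_control_probes: int = 20
    degraded_arrays: tuple[tuple[str, float], ...] = ()
    background_additive_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.n_probes <= 0:
            bad.append("n_probes")
        if self.replicates_per_probe <= 0:
            bad.append("replicates_per_probe")
        if any(n <= 0 for n in self.n_arrays_per_group):
            bad.append("n_arrays_per_group")
        if not 0 <= self.n_de_probes <= self.n_probes:
            bad.append("n_de_probes")
        if not 0.0 <= self.detection_miss_rate <= 1.0:
            bad.append("detection_miss_rate")
        if self.baseline_log2_sd < 0 or self.noise_log2_sd < 0:
            bad.append("noise sds")
        if self.background_additive_sd < 0:
            bad.append("background_additive_sd")
        if self.n_control_probes < 0:
            bad.append("n_control_probes")
        for _, extra in self.degraded_arrays:
            if not 0.0 <= extra <= 1.0:
                bad.append("degraded_arrays")
                break
        if bad:
            raise ValidationError(f"invalid simulation config fields: {bad}")


@dataclass
class GroundTruth:
    """What was planted: DE probe names, true group means, detection counts."""

    de_probe_names: set[str]
    true_means: pd.DataFrame  # probes x (ALK_NEG, ALK_POS) log2 means
    detected_per_array: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "de_probe_names": sorted(self.de_probe_names),
            "true_means": self.true_means.to_dict(),
            "detected_per_array": self.detected_per_array,
        }


def _sample_ids(cfg: SimulationConfig) -> list[tuple[str, str]]:
    n_pos, n_neg = cfg.n_arrays_per_group
    out = [(f"ALKpos_{i + 1:02d}", GROUP_POS) for i in range(n_pos)]
    out += [(f"ALKneg_{i + 1:02d}", GROUP_NEG) for i in range(n_neg)]
    return out


def simulate_fe_dataset(
    cfg: SimulationConfig,
) -> tuple[list[ArrayScan], SampleSheet, GroundTruth]:
    """Generate two groups of FE-style arrays with planted ground truth.

    Deterministic given ``cfg.seed``.  Returns the scans, a sample sheet
    (file names are ``<sample_id>.txt``, written only by the caller), and the
    planted truth.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    probes = [f"hsa-sim-miR-{i + 1:04d}" for i in range(cfg.n_probes)]
    controls = [f"NC_ctrl_{i + 1:03d}" for i in range(cfg.n_control_probes)]
    de_idx = np.sort(
        rng.choice(cfg.n_probes, size=cfg.n_de_probes, replace=False)
    )
    de_names = {probes[i] for i in de_idx}

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_probes)
    mean_neg = baseline.copy()
    mean_pos = baseline.copy()
    mean_pos[de_idx] -= cfg.de_log2_effect  # planted probes down in ALK+
    true_means = pd.DataFrame(
        {GROUP_NEG: mean_neg, GROUP_POS: mean_pos}, index=probes
    )

    extra_miss = dict(cfg.degraded_arrays)
    flag_names = tuple(DEFAULT_FLAG_COLUMNS)
    rep = cfg.replicates_per_probe
    n_hsa_spots = cfg.n_probes * rep
    n_ctrl_spots = cfg.n_control_probes * rep

    scans: list[ArrayScan] = []
    truth_counts: dict[str, int] = {}
    rows_sheet = []
    for sample_id, group in _sample_ids(cfg):
        mu = mean_neg if group == GROUP_NEG else mean_pos
        log2_int = np.repeat(mu, rep) + rng.normal(0, cfg.noise_log2_sd, n_hsa_spots)
        signal = 2.0**log2_int
        if cfg.background_additive_sd > 0:
            signal = signal + rng.normal(0, cfg.background_additive_sd, n_hsa_spots)
        miss = min(1.0, cfg.detection_miss_rate + extra_miss.get(sample_id, 0.0))
        detected = rng.random(n_hsa_spots) >= miss

        ctrl_signal = 2.0 ** rng.normal(
            cfg.baseline_log2_mean, cfg.baseline_log2_sd, n_ctrl_spots
        )

        frame = pd.DataFrame(
            {
                "spot_index": np.arange(n_hsa_spots + n_ctrl_spots, dtype=np.int64),
                "probe_name": np.concatenate(
                    [np.repeat(probes, rep), np.repeat(controls, rep)]
                ),
                "control_type": np.concatenate(
                    [
                        np.zeros(n_hsa_spots, dtype=np.int64),
                        np.ones(n_ctrl_spots, dtype=np.int64),
                    ]
                ),
                "signal_bgsub": np.concatenate([signal, ctrl_signal]),
            }
        )
        all_detected = np.concatenate([detected, np.ones(n_ctrl_spots, dtype=bool)])
        frame["well_above_background"] = all_detected
        frame["saturated"] = False
        frame["nonuniform_outlier"] = False
        frame["population_outlier"] = False
        frame["manual_flag"] = False
        scans.append(ArrayScan(sample_id, frame, flag_names, group))
        truth_counts[sample_id] = int(detected.sum())
        rows_sheet.append({"file": f"{sample_id}.txt", "sample_id": sample_id, "group": group})

    sheet = SampleSheet(pd.DataFrame(rows_sheet))
    truth = GroundTruth(de_names, true_means, truth_counts)
    return scans, sheet, truth


def write_dataset(
    scans: Sequence[ArrayScan],
    sheet: SampleSheet,
    truth: GroundTruth,
    out_dir: str | Path,
) -> None:
    """Write FE files, the sample sheet and the ground truth under a directory."""
    import json

    from .fe_io import write_fe_file

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_id = {s.sample_id: s for s in scans}
    for row in sheet.frame.itertuples(index=False):
        write_fe_file(by_id[row.sample_id], out / row.file)
    sheet.write(out / "samplesheet.csv")
    (out / "ground_truth.json").write_text(json.dumps(truth.to_dict(), indent=2))


def simulate_ct_table(
    n_samples: int,
    reference_cts: Sequence[float],
    target_delta_cts: Sequence[float],
    noise_sd: float,
    seed: int,
    target_gene: str = "ALK",
) -> CtTable:
    """Ct table with planted ΔCt structure: target = geomean(refs) + ΔCt + noise."""
    if n_samples != len(target_delta_cts):
        raise ValidationError("n_samples must equal len(target_delta_cts)")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    refs = np.asarray(reference_cts, dtype=float)
    if refs.size == 0 or np.any(refs <= 0):
        raise ValidationError("reference Cts must be positive and non-empty")
    rng = np.random.default_rng(seed)
    ref_names = (
        ["18S", "GAPDH", "UBC"] if refs.size == 3 else [f"RG{i + 1}" for i in range(refs.size)]
    )
    geo = float(np.exp(np.mean(np.log(refs))))
    data = {}
    for g, ct0 in zip(ref_names, refs):
        data[g] = ct0 + rng.normal(0, noise_sd, n_samples)
    data[target_gene] = (
        geo + np.asarray(target_delta_cts, dtype=float) + rng.normal(0, noise_sd, n_samples)
    )
    ct = pd.DataFrame(data, index=[f"sample_{i + 1}" for i in range(n_samples)])
    return CtTable(ct=ct, target=target_gene, references=tuple(ref_names))


def simulate_plate(
    kind: str,
    design: Mapping[str, int],
    true_effects: Mapping[str, float],
    noise_cv: float,
    seed: int,
) -> PlateReading:
    """Plate with planted per-condition effects.

    ``design`` maps condition → number of replicate wells; ``true_effects``
    maps condition → relative effect (1.0 when absent).  Luciferase wells get
    paired firefly/renilla counts, MTT wells paired A595/A655 absorbances;
    multiplicative noise with coefficient of variation ``noise_cv``.
    """
    if kind not in ("luciferase", "mtt"):
        raise ValidationError(f"unknown plate kind '{kind}'")
    if not design:
        raise ValidationError("plate design must be non-empty")
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    base_firefly, base_renilla = 1.0e6, 5.0e5
    base_signal, background = 1.0, 0.1
    rows = []
    for cond, n_rep in design.items():
        if n_rep <= 0:
            raise ValidationError(f"condition '{cond}' needs >= 1 replicate")
        eff = float(true_effects.get(cond, 1.0))
        for r in range(n_rep):
            if kind == "luciferase":
                rows.append(
                    {
                        "condition": cond,
                        "replicate": r,
                        "firefly": base_firefly * eff * (1 + noise_cv * rng.standard_normal()),
                        "renilla": base_renilla * (1 + noise_cv * rng.standard_normal()),
                    }
                )
            else:
                rows.append(
                    {
                        "condition": cond,
                        "replicate": r,
                        "a595": background
                        + base_signal * eff * (1 + noise_cv * rng.standard_normal()),
                        "a655": background,
                    }
                )
    return PlateReading(wells=pd.DataFrame(rows), kind=kind)
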