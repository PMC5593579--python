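"""End-to-end orchestration of the analysis from a config.

Stage order is fixed: read FE files → restrict to 'hsa' probes → detection
calls → probe filter (per-group detected-spot counts) → array exclusion
(MEAN − k·SD) → replicate averaging → floored log2 → between-array
normalization (quantile for the cell-line preset, scale for the tumor
preset) → Welch differential expression → Ward clustering of the significant
probes → candidate prioritization.  Every threshold in force is echoed in
the run report so a run is auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import clustering, diffexp, normalization, qc
from .errors import PipelineStageError, ValidationError
from .fe_io import ArrayScan, SampleSheet, read_fe_file, restrict_to_prefix
from .prioritization import CandidateAnnotation, select_candidates
from .synthetic import SimulationConfig, simulate_fe_dataset

log = logging.getLogger("mirpipe")

PRESETS = {
    "cell_lines": {"normalization": "quantile"},
    "tumors": {"normalization": "scale"},
}


@dataclass
class PipelineConfig:
    """All thresholds of the analysis; defaults match the published design."""

    sample_sheet: str | None = None
    preset: str | None = None
    hsa_prefix: str = "hsa"
    require_true: tuple[str, ...] = qc.DEFAULT_POLICY.require_true
    require_false: tuple[str, ...] = qc.DEFAULT_POLICY.require_false
    min_detected: int = 5
    sd_multiplier: float = 2.0
    log2_floor: float = 1.0
    normalization: str = "quantile"  # or "scale"
    scale_mode: str = "multiplicative"
    alpha: float = 0.05
    ward_variant: str = "D2"
    fold_change_threshold: float = 2.0
    out_dir: str = "mirpipe_out"
    seed: int = 0
    simulation: SimulationConfig | None = None

    def __post_init__(self):
        if self.preset is not None:
            if self.preset not in PRESETS:
                raise ValidationError(f"unknown preset '{self.preset}'")
            self.normalization = PRESETS[self.preset]["normalization"]
        if self.normalization not in ("quantile", "scale"):
            raise ValidationError(f"unknown normalization '{self.normalization}'")

    @property
    def policy(self) -> qc.DetectionPolicy:
        return qc.DetectionPolicy(tuple(self.require_true), tuple(self.require_false))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            if "n_arrays_per_group" in sim:
                sim["n_arrays_per_group"] = tuple(sim["n_arrays_per_group"])
            if "degraded_arrays" in sim:
                sim["degraded_arrays"] = tuple(
                    (a, float(b)) for a, b in sim["degraded_arrays"]
                )
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def echo(self) -> dict:
        d = asdict(self)
        if self.simulation is not None:
            d["simulation"] = asdict(self.simulation)
        return d


@dataclass
class RunReport:
    """Machine-readable account of one pipeline run."""

    qc_report: dict = field(default_factory=dict)
    stage_dimensions: dict = field(default_factory=dict)
    n_significant: int = 0
    n_down_in_alk_pos: int = 0
    candidates: list[str] = field(default_factory=list)
    file_manifest: dict[str, str] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "qc_report": self.qc_report,
                "stage_dimensions": self.stage_dimensions,
                "n_significant": self.n_significant,
                "n_down_in_alk_pos": self.n_down_in_alk_pos,
                "candidates": self.candidates,
                "file_manifest": self.file_manifest,
                "config": self.config,
            },
            indent=2,
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_scans(cfg: PipelineConfig) -> tuple[list[ArrayScan], Mapping[str, str]]:
    """Load arrays from the sample sheet, or simulate them when none is given."""
    if cfg.sample_sheet is not None:
        sheet = SampleSheet.read(cfg.sample_sheet)
        base = Path(cfg.sample_sheet).parent
        scans = []
        for path, (_, sid, group) in zip(
            sheet.resolve_paths(base), sheet.frame.itertuples(index=False)
        ):
            scans.append(read_fe_file(path, sample_id=sid, group_label=group))
        return scans, sheet.design
    sim = cfg.simulation or SimulationConfig(seed=cfg.seed)
    scans, sheet, _ = simulate_fe_dataset(sim)
    return scans, sheet.design


def run_full_analysis(
    cfg: PipelineConfig,
    scans: Sequence[ArrayScan] | None = None,
    design: Mapping[str, str] | None = None,
    annotations: Sequence[CandidateAnnotation] | None = None,
    write_outputs: bool = True,
) -> RunReport:
    """Run the full cascade; optionally on pre-loaded scans.

    Writes the differential table, dendrograms, heatmap orders, QC report and
    run report under ``cfg.out_dir`` unless ``write_outputs`` is False.  Any
    stage failure raises :class:`PipelineStageError` naming the stage, and
    partial outputs are removed.
    """
    report = RunReport(config=cfg.echo())
    out = Path(cfg.out_dir)
    written: list[Path] = []

    current = {"stage": "load"}

    def stage(name):
        current["stage"] = name
        log.info("stage %s (thresholds: min_detected=%s sd_multiplier=%s "
                 "log2_floor=%s normalization=%s alpha=%s)",
                 name, cfg.min_detected, cfg.sd_multiplier, cfg.log2_floor,
                 cfg.normalization, cfg.alpha)

    try:
        stage("load")
        if scans is None:
            scans, design = load_scans(cfg)
        if design is None:
            design = {s.sample_id: s.group_label for s in scans}
        scans = list(scans)
        report.stage_dimensions["arrays_input"] = len(scans)

        stage("restrict_hsa")
        hsa = [restrict_to_prefix(s, cfg.hsa_prefix) for s in scans]
        report.stage_dimensions["hsa_spots_per_array"] = {
            s.sample_id: s.n_spots for s in hsa
        }

        stage("detection")
        policy = cfg.policy
        counts = qc.count_detected_per_array(scans, policy, cfg.hsa_prefix)

        stage("probe_filter")
        kept_probes, qreport = qc.filter_probes_by_group_detection(
            scans, design, policy, cfg.min_detected, cfg.hsa_prefix
        )
        qreport.detected_per_array = counts

        stage("array_filter")
        kept_ids, removed_ids, threshold = qc.remove_low_count_arrays(
            counts, cfg.sd_multiplier
        )
        qreport.removed_arrays = removed_ids
        qreport.array_threshold = threshold
        qreport.parameters.update(
            {"sd_multiplier": cfg.sd_multiplier, "policy": {
                "require_true": list(policy.require_true),
                "require_false": list(policy.require_false)}}
        )
        kept_scans = [s for s in hsa if s.sample_id in kept_ids]
        design = {k: v for k, v in design.items() if k in kept_ids}
        report.qc_report = qreport.to_dict()
        report.stage_dimensions["arrays_kept"] = len(kept_scans)
        report.stage_dimensions["probes_kept"] = len(kept_probes)

        stage("averaging")
        matrix = qc.average_replicates(kept_scans, kept_probes, policy)
        report.stage_dimensions["matrix_raw"] = list(matrix.shape)

        stage("log2")
        matrix = normalization.log2_transform(matrix, cfg.log2_floor)

        stage("normalize")
        if cfg.normalization == "quantile":
            matrix = normalization.quantile_normalize(matrix)
        else:
            matrix = normalization.scale_normalize(matrix, cfg.scale_mode)
        report.stage_dimensions["matrix_normalized"] = list(matrix.shape)

        stage("diffexp")
        table = diffexp.run_diffexp(matrix, design, cfg.alpha)
        report.n_significant = table.n_significant
        report.n_down_in_alk_pos = table.n_down_in_alk_pos

        stage("clustering")
        sig = table.significant_records()["probe_name"].tolist()
        dend_rows = dend_cols = None
        if len(sig) >= 2:
            sub = matrix.values.loc[sig]
            d_rows = clustering.euclidean_distances(sub.to_numpy(), "rows")
            dend_rows = clustering.ward_linkage(d_rows, sig, cfg.ward_variant)
            if sub.shape[1] >= 2:
                d_cols = clustering.euclidean_distances(sub.to_numpy(), "columns")
                dend_cols = clustering.ward_linkage(
                    d_cols, list(sub.columns), cfg.ward_variant
                )

        stage("prioritization")
        if annotations is None:
            sig_down = table.significant_records()
            sig_down = sig_down[sig_down["direction"] == diffexp.DOWN_IN_ALK_POS]
            annotations = [
                CandidateAnnotation(p) for p in sig_down["probe_name"]
            ]
        candidates = select_candidates(table, annotations, cfg.fold_change_threshold)
        report.candidates = candidates["probe_name"].tolist()

        if write_outputs:
            stage("write")
            out.mkdir(parents=True, exist_ok=True)

            def emit(name: str, writer):
                path = out / name
                writer(path)
                written.append(path)
                report.file_manifest[name] = _sha256(path)

            emit("diffexp.tsv", table.to_tsv)
            emit(
                "normalized_matrix.tsv",
                lambda p: matrix.values.to_csv(p, sep="\t"),
            )
            emit(
                "qc_report.json",
                lambda p: p.write_text(json.dumps(qreport.to_dict(), indent=2)),
            )
            emit(
                "candidates.tsv",
                lambda p: candidates.to_csv(p, sep="\t", index=False),
            )
            if dend_rows is not None:
                emit(
                    "dendrogram_rows.nwk",
                    lambda p: p.write_text(dend_rows.to_newick() + "\n"),
                )
                emit(
                    "heatmap_row_order.txt",
                    lambda p: p.write_text("\n".join(dend_rows.leaf_order()) + "\n"),
                )
            if dend_cols is not None:
                emit(
                    "dendrogram_columns.nwk",
                    lambda p: p.write_text(dend_cols.to_newick() + "\n"),
                )
                emit(
                    "heatmap_column_order.txt",
                    lambda p: p.write_text("\n".join(dend_cols.leaf_order()) + "\n"),
                )
            (out / "run_report.json").write_text(report.to_json())
        return report
    except PipelineStageError:
        raise
    except Exception as exc:  # attribute the failure to the active stage
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineStageError(current["stage"], exc) from exc
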