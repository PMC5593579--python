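"""Reading and writing Feature-Extraction-style spot tables.

An Agilent Feature Extraction (FE) run produces one tab-delimited text file per
array, with one row per spotted feature and columns for the probe name, a
control-type code (0 = experimental probe), the background-subtracted
fluorescence signal and a set of boolean quality flags.  Column names vary by
FE software version, so every reader/writer takes a *dialect*: a mapping from
canonical field names to the column headers found in the file.  The default
dialect uses the standard single-channel FE names (``ProbeName``,
``ControlType``, ``gBGSubSignal``, ``gIsWellAboveBG`` ...).

Human miRNA probes are recognized by their ``hsa`` name prefix; everything
else on the array (corner markers, spike-ins, negative controls) is a control
feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: canonical QC flag names -> default FE column headers.
#: ``well_above_background`` must be true and the remaining flags false for a
#: spot to count as detected under the default policy.
DEFAULT_FLAG_COLUMNS: Mapping[str, str] = {
    "well_above_background": "gIsWellAboveBG",
    "saturated": "gIsSaturated",
    "nonuniform_outlier": "gIsFeatNonUnifOL",
    "population_outlier": "gIsFeatPopnOL",
    "manual_flag": "IsManualFlag",
}


@dataclass(frozen=True)
class FeDialect:
    """Column-name mapping for one FE software flavour."""

    probe_name: str = "ProbeName"
    control_type: str = "ControlType"
    signal_bgsub: str = "gBGSubSignal"
    flags: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_FLAG_COLUMNS))


DEFAULT_DIALECT = FeDialect()

_CORE_COLUMNS = ("spot_index", "probe_name", "control_type", "signal_bgsub")


@dataclass(frozen=True)
class SpotRecord:
    """One spotted feature on one array."""

    probe_name: str
    control_type: int
    signal_bgsub: float
    qc_flags: Mapping[str, bool]
    spot_index: int

    @property
    def is_control(self) -> bool:
        return self.control_type != 0


class ArrayScan:
    """One array's spot-level table.

    Spots live in a DataFrame (``frame``) with canonical columns
    ``spot_index, probe_name, control_type, signal_bgsub`` plus one boolean
    column per QC flag present in the source file.  Flags absent from the
    source are recorded as absent rather than defaulted, so a detection policy
    that needs them fails loudly.
    """

    def __init__(
        self,
        sample_id: str,
        frame: pd.DataFrame,
        flag_names: Sequence[str] = (),
        group_label: str | None = None,
    ):
        if not sample_id:
            raise ValidationError("sample_id must be non-empty")
        frame = frame.reset_index(drop=True)
        for col in _CORE_COLUMNS:
            if col not in frame.columns:
                raise ValidationError(f"ArrayScan frame missing column '{col}'")
        if frame["spot_index"].duplicated().any():
            raise ValidationError(f"duplicate spot_index in array '{sample_id}'")
        self.sample_id = sample_id
        self.group_label = group_label
        self.flag_names = tuple(flag_names)
        self.frame = frame[list(_CORE_COLUMNS) + list(self.flag_names)].copy()
        self.frame["probe_name"] = self.frame["probe_name"].astype(str)
        self.frame["control_type"] = self.frame["control_type"].astype(np.int64)
        self.frame["signal_bgsub"] = self.frame["signal_bgsub"].astype(float)
        for f in self.flag_names:
            self.frame[f] = self.frame[f].astype(bool)

    # -- convenience -------------------------------------------------------
    @classmethod
    def from_spots(
        cls,
        sample_id: str,
        spots: Iterable[SpotRecord],
        group_label: str | None = None,
    ) -> "ArrayScan":
        spots = list(spots)
        flag_names: tuple[str, ...] = tuple(spots[0].qc_flags) if spots else ()
        rows = {
            "spot_index": [s.spot_index for s in spots],
            "probe_name": [s.probe_name for s in spots],
            "control_type": [s.control_type for s in spots],
            "signal_bgsub": [s.signal_bgsub for s in spots],
        }
        for f in flag_names:
            rows[f] = [bool(s.qc_flags[f]) for s in spots]
        frame = pd.DataFrame(rows, columns=list(_CORE_COLUMNS) + list(flag_names))
        if not spots:
            frame = pd.DataFrame(columns=list(_CORE_COLUMNS))
        return cls(sample_id, frame, flag_names, group_label)

    @property
    def spots(self) -> list[SpotRecord]:
        out = []
        for row in self.frame.itertuples(index=False):
            d = row._asdict()
            out.append(
                SpotRecord(
                    probe_name=d["probe_name"],
                    control_type=int(d["control_type"]),
                    signal_bgsub=float(d["signal_bgsub"]),
                    qc_flags={f: bool(d[f]) for f in self.flag_names},
                    spot_index=int(d["spot_index"]),
                )
            )
        return out

    @property
    def n_spots(self) -> int:
        return len(self.frame)

    @property
    def probe_names(self) -> pd.Series:
        return self.frame["probe_name"]

    def __len__(self) -> int:
        return self.n_spots

    def __eq__(self, other) -> bool:
        if not isinstance(other, ArrayScan):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.group_label == other.group_label
            and self.flag_names == other.flag_names
            and self.frame.equals(other.frame)
        )

    def __repr__(self) -> str:
        return (
            f"ArrayScan(sample_id={self.sample_id!r}, n_spots={self.n_spots}, "
            f"group={self.group_label!r})"
        )


def read_fe_file(
    path: str | Path,
    dialect: FeDialect = DEFAULT_DIALECT,
    sample_id: str | None = None,
    group_label: str | None = None,
) -> ArrayScan:
    """Parse one FE-style tab-delimited file into an :class:`ArrayScan`.

    Raises :class:`FormatError` if a mandatory column (probe name, control
    type, signal) is missing under the dialect, or if a numeric cell cannot be
    parsed (the error names the 1-based data row).
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for canon, col in (
        ("probe_name", dialect.probe_name),
        ("control_type", dialect.control_type),
        ("signal_bgsub", dialect.signal_bgsub),
    ):
        if col not in raw.columns:
            raise FormatError(
                f"{path.name}: missing mandatory column '{col}' ({canon})"
            )

    def _numeric(col: str, caster):
        # float() rather than pd.to_numeric: the latter can be 1 ulp off,
        # breaking lossless round trips
        out = np.empty(len(raw), dtype=float)
        for i, cell in enumerate(raw[col]):
            try:
                out[i] = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path.name}: unparseable numeric value {cell!r} "
                    f"in column '{col}', data row {i + 1}"
                ) from None
        return caster(pd.Series(out, index=raw.index))

    frame = pd.DataFrame(
        {
            "spot_index": np.arange(len(raw), dtype=np.int64),
            "probe_name": raw[dialect.probe_name].astype(str),
        }
    )
    if len(raw):
        frame["control_type"] = _numeric(dialect.control_type, lambda v: v.astype(np.int64))
        frame["signal_bgsub"] = _numeric(dialect.signal_bgsub, lambda v: v.astype(float))
    else:
        frame["control_type"] = np.array([], dtype=np.int64)
        frame["signal_bgsub"] = np.array([], dtype=float)

    flag_names = []
    for canon, col in dialect.flags.items():
        if col in raw.columns:
            if len(raw):
                frame[canon] = _numeric(col, lambda v: v.astype(np.int64) != 0)
            else:
                frame[canon] = np.array([], dtype=bool)
            flag_names.append(canon)

    sid = sample_id if sample_id is not None else path.stem
    return ArrayScan(sid, frame, flag_names, group_label)


def write_fe_file(
    scan: ArrayScan, path: str | Path, dialect: FeDialect = DEFAULT_DIALECT
) -> None:
    """Write ``scan`` as a tab-delimited FE-style file (lossless round trip)."""
    path = Path(path)
    out = pd.DataFrame(
        {
            dialect.probe_name: scan.frame["probe_name"],
            dialect.control_type: scan.frame["control_type"],
            dialect.signal_bgsub: scan.frame["signal_bgsub"].map(
                lambda v: repr(float(v))  # shortest exact decimal round trip
            ),
        }
    )
    for canon in scan.flag_names:
        out[dialect.flags[canon]] = scan.frame[canon].astype(int)
    out.to_csv(path, sep="\t", index=False, encoding="utf-8")


def restrict_to_prefix(scan: ArrayScan, prefix: str) -> ArrayScan:
    """Keep only spots whose probe name starts with ``prefix`` (order kept).

    The study keeps human miRNA probes via the ``hsa`` prefix.
    """
    if not prefix:
        raise ValidationError("prefix must be non-empty")
    mask = scan.frame["probe_name"].str.startswith(prefix)
    return ArrayScan(
        scan.sample_id,
        scan.frame.loc[mask].reset_index(drop=True),
        scan.flag_names,
        scan.group_label,
    )


@dataclass
class SampleSheet:
    """Maps FE files to sample ids and their group (e.g. ALK_POS / ALK_NEG)."""

    frame: pd.DataFrame  # columns: file, sample_id, group

    def __post_init__(self):
        for col in ("file", "sample_id", "group"):
            if col not in self.frame.columns:
                raise ValidationError(f"sample sheet missing column '{col}'")
        if self.frame["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in sample sheet")
        groups = set(self.frame["group"])
        if len(groups) > 2:
            raise ValidationError(
                f"sample sheet must use at most two group labels, got {sorted(groups)}"
            )

    @classmethod
    def read(cls, path: str | Path) -> "SampleSheet":
        path = Path(path)
        frame = pd.read_csv(path, dtype=str)
        sheet = cls(frame)
        base = path.parent
        for f in sheet.frame["file"]:
            if not (base / f).exists() and not Path(f).exists():
                raise ValidationError(f"sample sheet references missing file '{f}'")
        return sheet

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @property
    def design(self) -> dict[str, str]:
        """sample_id -> group label."""
        return dict(zip(self.frame["sample_id"], self.frame["group"]))

    def resolve_paths(self, base: str | Path) -> list[Path]:
        base = Path(base)
        return [
            Path(f) if Path(f).exists() else base / f for f in self.frame["file"]
        ]
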