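import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mirpipe import ArrayScan, SpotRecord

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

ALL_FLAGS = (
    "well_above_background",
    "saturated",
    "nonuniform_outlier",
    "population_outlier",
    "manual_flag",
)


def make_spot(
    probe,
    signal=100.0,
    idx=0,
    control_type=0,
    detected=True,
    **flag_overrides,
) -> SpotRecord:
    """A spot whose flags pass (detected) or fail well-above-background."""
    flags = {f: False for f in ALL_FLAGS}
    flags["well_above_background"] = detected
    flags.update(flag_overrides)
    return SpotRecord(
        probe_name=probe,
        control_type=control_type,
        signal_bgsub=signal,
        qc_flags=flags,
        spot_index=idx,
    )


def make_scan(sample_id, spots, group=None) -> ArrayScan:
    return ArrayScan.from_spots(sample_id, spots, group_label=group)


@pytest.fixture
def toy_scan() -> ArrayScan:
    """Six spots: three hsa probes in duplicate plus two controls."""
    spots = [
        make_spot("hsa-miR-21-5p", 100.0, 0),
        make_spot("hsa-miR-21-5p", 120.0, 1),
        make_spot("hsa-miR-424-5p", 50.0, 2),
        make_spot("hsa-miR-424-5p", 54.0, 3),
        make_spot("hsa-miR-503-5p", 8.0, 4),
        make_spot("hsa-miR-503-5p", 10.0, 5),
        make_spot("BrightCorner", 5000.0, 6, control_type=1),
        make_spot("NegativeControl", 1.0, 7, control_type=-1),
    ]
    return make_scan("arr1", spots)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def two_group_scans():
    """4 + 4 arrays, 3 probes in duplicate, all detected, fixed signals."""
    scans = []
    design = {}
    base = {"hsa-p1": 100.0, "hsa-p2": 50.0, "hsa-p3": 20.0}
    for g, glabel in (("A", "ALK_NEG"), ("B", "ALK_POS")):
        for i in range(4):
            sid = f"{g}{i}"
            spots = []
            idx = 0
            for probe, sig in base.items():
                for r in range(2):
                    spots.append(make_spot(probe, sig + 2 * i + r, idx))
                    idx += 1
            scans.append(make_scan(sid, spots, glabel))
            design[sid] = glabel
    return scans, design
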