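"""Detection calls, probe/array filtering and replicate averaging."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirpipe import (
    DetectionPolicy,
    average_replicates,
    call_detected,
    count_detected_per_array,
    filter_probes_by_group_detection,
    remove_low_count_arrays,
)
from mirpipe.errors import ConfigurationError, DataIntegrityError, ValidationError

from conftest import make_scan, make_spot


class TestCallDetected:
    def test_clean_experimental_spot_detected(self):
        scan = make_scan("s", [make_spot("hsa-a", 10.0, 0)])
        assert call_detected(scan).tolist() == [True]

    def test_saturated_spot_not_detected(self):
        scan = make_scan("s", [make_spot("hsa-a", 10.0, 0, saturated=True)])
        assert call_detected(scan).tolist() == [False]

    def test_control_spot_never_detected(self):
        scan = make_scan("s", [make_spot("ctrl", 10.0, 0, control_type=1)])
        assert call_detected(scan).tolist() == [False]

    def test_below_background_not_detected(self):
        scan = make_scan("s", [make_spot("hsa-a", 10.0, 0, detected=False)])
        assert call_detected(scan).tolist() == [False]

    def test_policy_missing_flag_raises(self):
        scan = make_scan("s", [make_spot("hsa-a", 10.0, 0)])
        policy = DetectionPolicy(require_true=("well_above_background", "nonexistent_flag"))
        with pytest.raises(ConfigurationError, match="nonexistent_flag"):
            call_detected(scan, policy)


class TestCountDetected:
    def test_counts_hsa_only(self, toy_scan):
        counts = count_detected_per_array([toy_scan])
        assert counts == {"arr1": 6}

    def test_all_failing_gives_zero(self):
        scan = make_scan(
            "s", [make_spot(f"hsa-{i}", 1.0, i, detected=False) for i in range(6)]
        )
        assert count_detected_per_array([scan]) == {"s": 0}

    def test_mixed_partial_detection(self):
        spots = [make_spot(f"hsa-{i}", 1.0, i, detected=i < 3) for i in range(6)]
        assert count_detected_per_array([make_scan("s", spots)]) == {"s": 3}


class TestRemoveLowCountArrays:
    def test_mean_minus_2sd_hand_example(self):
        """Fifteen arrays at 100 detected spots, one at 10: sample mean
        94.375, sample sd 22.5, threshold 49.375, only the low array removed."""
        counts = {f"a{i}": 100 for i in range(15)}
        counts["low"] = 10
        kept, removed, threshold = remove_low_count_arrays(counts)
        assert threshold == pytest.approx(49.375)
        assert removed == ["low"]
        assert len(kept) == 15

    def test_equal_counts_nothing_removed(self):
        counts = {f"a{i}": 50 for i in range(4)}
        kept, removed, threshold = remove_low_count_arrays(counts)
        assert removed == []
        assert threshold == pytest.approx(50.0)

    def test_fewer_than_two_arrays_rejected(self):
        with pytest.raises(ValidationError):
            remove_low_count_arrays({"only": 100})

    def test_permutation_invariant(self, rng):
        counts = {f"a{i}": int(c) for i, c in enumerate(rng.integers(10, 200, 12))}
        ref = remove_low_count_arrays(counts)
        items = list(counts.items())
        rng.shuffle(items)
        out = remove_low_count_arrays(dict(items))
        assert set(ref[0]) == set(out[0]) and set(ref[1]) == set(out[1])
        assert ref[2] == pytest.approx(out[2])


def _group_scans(per_probe_detected):
    """Two groups x 2 arrays; per_probe_detected[probe] = (detA, detB) counts
    out of 4 replicate spots per group (2 arrays x 2 replicates)."""
    scans, design = [], {}
    for g, glabel in (("A", "ALK_NEG"), ("B", "ALK_POS")):
        for a in range(2):
            sid = f"{g}{a}"
            spots = []
            idx = 0
            for probe, (da, db) in per_probe_detected.items():
                want = da if g == "A" else db
                for r in range(2):
                    spot_rank = a * 2 + r
                    spots.append(
                        make_spot(probe, 100.0, idx, detected=spot_rank < want)
                    )
                    idx += 1
            scans.append(make_scan(sid, spots, glabel))
            design[sid] = glabel
    return scans, design


class TestProbeFilter:
    def test_boundary_five_detected_kept(self):
        """'Less than 5' is exclusive: exactly 5 in a 8-replicate design kept."""
        scans, design = [], {}
        for g, glabel in (("A", "ALK_NEG"), ("B", "ALK_POS")):
            for a in range(4):
                sid = f"{g}{a}"
                # 2 replicates per array; probe detected in 5 of the 8 spots
                spots = [
                    make_spot("hsa-p", 50.0, r, detected=(a * 2 + r) < 5)
                    for r in range(2)
                ]
                scans.append(make_scan(sid, spots, glabel))
                design[sid] = glabel
        kept, report = filter_probes_by_group_detection(scans, design)
        assert kept == ["hsa-p"]
        assert report.n_probes_removed == 0

    def test_low_count_in_one_group_removed(self):
        """Plenty detected in one group cannot rescue a probe failing the other."""
        scans, design = _group_scans({"hsa-p": (4, 3)})
        kept, _ = filter_probes_by_group_detection(scans, design, min_detected=3)
        assert kept == ["hsa-p"]
        kept, _ = filter_probes_by_group_detection(scans, design, min_detected=4)
        assert kept == []

    def test_eight_probe_fixture_exact_counts(self):
        """Exactly 3 of 8 probes fall under the threshold in one group."""
        table = {
            f"hsa-p{i}": (4, 4) for i in range(5)
        }  # kept at min_detected=4
        table.update({f"hsa-bad{i}": (4, 2) for i in range(3)})
        scans, design = _group_scans(table)
        kept, report = filter_probes_by_group_detection(
            scans, design, min_detected=4
        )
        assert report.n_probes_kept == 5
        assert report.n_probes_removed == 3
        assert report.n_probes_total == 8

    def test_monotone_in_min_detected(self):
        table = {f"hsa-p{i}": (i % 5, 4) for i in range(10)}
        scans, design = _group_scans(table)
        prev = None
        for k in range(0, 5):
            kept, _ = filter_probes_by_group_detection(scans, design, min_detected=k)
            if prev is not None:
                assert set(kept) <= set(prev)
            prev = kept

    def test_group_with_zero_arrays_rejected(self):
        scans, design = _group_scans({"hsa-p": (4, 4)})
        design = {k: "ALK_NEG" for k in design}
        with pytest.raises(ValidationError):
            filter_probes_by_group_detection(scans, design)


class TestAverageReplicates:
    def test_duplicate_mean(self):
        scan = make_scan(
            "s", [make_spot("hsa-p", 100.0, 0), make_spot("hsa-p", 120.0, 1)]
        )
        m = average_replicates([scan], ["hsa-p"])
        assert m.values.loc["hsa-p", "s"] == pytest.approx(110.0)
        assert m.detection_counts.loc["hsa-p", "s"] == 2

    def test_single_spot_identity(self):
        scan = make_scan("s", [make_spot("hsa-p", 42.5, 0)])
        m = average_replicates([scan], ["hsa-p"])
        assert m.values.loc["hsa-p", "s"] == 42.5

    def test_undetected_spots_still_averaged(self):
        scan = make_scan(
            "s",
            [
                make_spot("hsa-p", 100.0, 0),
                make_spot("hsa-p", 0.0, 1, detected=False),
            ],
        )
        m = average_replicates([scan], ["hsa-p"])
        assert m.values.loc["hsa-p", "s"] == pytest.approx(50.0)
        assert m.detection_counts.loc["hsa-p", "s"] == 1

    def test_missing_probe_names_probe_and_array(self):
        s1 = make_scan("s1", [make_spot("hsa-p", 1.0, 0)])
        s2 = make_scan("s2", [make_spot("hsa-q", 1.0, 0)])
        with pytest.raises(DataIntegrityError, match="hsa-p.*s2"):
            average_replicates([s1, s2], ["hsa-p"])


@given(extra=st.integers(min_value=0, max_value=3))
def test_lossless_cascade_when_everything_detected(extra):
    """With no detection misses nothing is removed at either filter level."""
    n_arrays = 3 + extra  # 3 arrays x 2 replicates = 6 >= min_detected
    scans, design = [], {}
    for g, glabel in (("A", "ALK_NEG"), ("B", "ALK_POS")):
        for a in range(n_arrays):
            sid = f"{g}{a}"
            spots = []
            for i in range(6):
                for r in range(2):
                    spots.append(make_spot(f"hsa-p{i}", 10.0 * (i + 1), i * 2 + r))
            scans.append(make_scan(sid, spots, glabel))
            design[sid] = glabel
    counts = count_detected_per_array(scans)
    kept_ids, removed_ids, _ = remove_low_count_arrays(counts)
    kept, report = filter_probes_by_group_detection(scans, design, min_detected=5)
    assert removed_ids == []
    assert report.n_probes_removed == 0
    assert len(kept) == 6
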