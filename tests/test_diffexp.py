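"""Welch testing, fold changes and the differential table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from mirpipe import (
    ExpressionMatrix,
    WelchDifferentialExpression,
    fold_change,
    run_diffexp,
    welch_t,
)
from mirpipe.diffexp import DOWN_IN_ALK_POS, FLAT, UP_IN_ALK_POS
from mirpipe.errors import ValidationError

small_samples = st.lists(
    st.floats(-50, 50, allow_nan=False, width=32), min_size=2, max_size=8
)


class TestWelchT:
    def test_hand_example(self):
        """x=[1,2,3] vs y=[4,5,6]: t = -3/sqrt(2/3), df = 4 exactly."""
        t, df, p = welch_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3 / np.sqrt(2 / 3), abs=1e-12)
        assert df == pytest.approx(4.0, abs=1e-12)
        assert p == pytest.approx(0.021311641128756713, abs=1e-12)

    def test_identical_samples(self):
        t, df, p = welch_t([2.0, 3.0, 4.0], [2.0, 3.0, 4.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_unbalanced_sizes_match_reference(self):
        x, y = [2.0, 2.5], [3.0, 3.5, 4.0]
        t, df, p = welch_t(x, y)
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert df == pytest.approx(ref.df, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_equal_means_p_one(self):
        t, df, p = welch_t([5.0, 5.0], [5.0, 5.0, 5.0])
        assert (t, p) == (0.0, 1.0)

    def test_zero_variance_unequal_means_raises(self):
        with pytest.raises(ValidationError, match="zero variance"):
            welch_t([5.0, 5.0], [7.0, 7.0])

    def test_group_of_one_rejected(self):
        with pytest.raises(ValidationError):
            welch_t([1.0], [2.0, 3.0])

    @given(x=small_samples, y=small_samples)
    def test_matches_reference_implementation(self, x, y):
        x, y = np.asarray(x), np.asarray(y)
        if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
            return
        t, df, p = welch_t(x, y)
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    @given(x=small_samples, y=small_samples, c=st.floats(-20, 20, allow_nan=False))
    def test_label_swap_and_shift_invariance(self, x, y, c):
        x, y = np.asarray(x, float), np.asarray(y, float)
        if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
            return
        t1, df1, p1 = welch_t(x, y)
        t2, df2, p2 = welch_t(y, x)
        assert t1 == pytest.approx(-t2, abs=1e-10)
        assert p1 == pytest.approx(p2, abs=1e-12)
        t3, _, p3 = welch_t(x + c, y + c)
        assert t3 == pytest.approx(t1, rel=1e-9, abs=1e-9)
        assert p3 == pytest.approx(p1, rel=1e-9, abs=1e-9)


class TestFoldChange:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (11.31, 8.73, 5.98),  # cell lines, strongly down in ALK+
            (11.69, 10.30, 2.62),  # tumors
            (5.56, 2.88, 6.41),  # cell lines
            (1.92, 0.27, 3.14),  # low-expression cell-line entry
        ],
    )
    def test_published_style_group_means(self, a, b, expected):
        fc, direction = fold_change(a, b)
        assert round(fc, 2) == pytest.approx(expected)
        assert direction == DOWN_IN_ALK_POS

    def test_equal_means_flat(self):
        fc, direction = fold_change(3.3, 3.3)
        assert fc == 1.0 and direction == FLAT

    def test_direction_flips_with_order(self):
        fc_ab, d_ab = fold_change(2.0, 5.0)
        fc_ba, d_ba = fold_change(5.0, 2.0)
        assert fc_ab == pytest.approx(fc_ba)
        assert (d_ab, d_ba) == (UP_IN_ALK_POS, DOWN_IN_ALK_POS)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            fold_change(np.nan, 1.0)

    @given(
        a=st.floats(-16, 16, allow_nan=False),
        b=st.floats(-16, 16, allow_nan=False),
    )
    def test_magnitude_symmetric_and_at_least_one(self, a, b):
        fc, _ = fold_change(a, b)
        fc_rev, _ = fold_change(b, a)
        assert fc == pytest.approx(fc_rev)
        assert fc >= 1.0
        assert fc == pytest.approx(2 ** abs(a - b), rel=1e-12)


def _matrix(values, samples, probes=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"hsa-p{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=probes, columns=samples), stage="normalized"
    )


class TestRunDiffexp:
    def setup_method(self):
        self.samples = ["n1", "n2", "n3", "p1", "p2", "p3"]
        self.design = {s: ("ALK_NEG" if s.startswith("n") else "ALK_POS") for s in self.samples}

    def test_identical_groups_zero_significant(self):
        rng = np.random.default_rng(0)
        half = rng.normal(8, 1, size=(20, 3))
        m = _matrix(np.hstack([half, half]), self.samples)
        table = run_diffexp(m, self.design)
        assert table.n_significant == 0
        assert (table.records["p_raw"] == 1.0).all()

    def test_planted_difference_detected_with_direction(self):
        rng = np.random.default_rng(1)
        base = rng.normal(8, 0.1, size=(10, 6))
        base[0, 3:] -= 3.0  # down in ALK+
        m = _matrix(base, self.samples)
        table = run_diffexp(m, self.design)
        top = table.records.iloc[0]
        assert top["probe_name"] == "hsa-p0"
        assert top["significant"]
        assert top["direction"] == DOWN_IN_ALK_POS
        assert table.n_down_in_alk_pos >= 1

    def test_sorted_by_p_with_name_tiebreak(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.normal(8, 1, size=(30, 6)), self.samples)
        rec = run_diffexp(m, self.design).records
        assert rec["p_raw"].is_monotonic_increasing
        # fold change consistent with the two means on every row
        np.testing.assert_allclose(
            rec["fold_change"],
            2 ** (rec["mean_alk_neg"] - rec["mean_alk_pos"]).abs(),
            atol=1e-9,
        )

    def test_bh_q_reported_not_used_for_selection(self):
        rng = np.random.default_rng(3)
        m = _matrix(rng.normal(8, 1, size=(50, 6)), self.samples)
        table = run_diffexp(m, self.design, alpha=0.05)
        rec = table.records
        assert (rec["q_bh"] >= rec["p_raw"] - 1e-12).all()
        assert table.n_significant == int((rec["p_raw"] < 0.05).sum())

    def test_group_with_one_array_rejected(self):
        m = _matrix(np.random.default_rng(0).normal(size=(5, 3)), ["n1", "n2", "p1"])
        design = {"n1": "ALK_NEG", "n2": "ALK_NEG", "p1": "ALK_POS"}
        with pytest.raises(ValidationError):
            run_diffexp(m, design)

    def test_label_swap_flips_direction_preserves_p(self):
        rng = np.random.default_rng(4)
        m = _matrix(rng.normal(8, 1, size=(15, 6)), self.samples)
        t1 = run_diffexp(m, self.design).records.set_index("probe_name")
        flipped = {
            s: ("ALK_POS" if g == "ALK_NEG" else "ALK_NEG")
            for s, g in self.design.items()
        }
        t2 = run_diffexp(m, flipped).records.set_index("probe_name")
        np.testing.assert_allclose(t1["p_raw"], t2.loc[t1.index, "p_raw"], atol=1e-12)
        np.testing.assert_allclose(
            t1["t_stat"], -t2.loc[t1.index, "t_stat"], atol=1e-12
        )
        np.testing.assert_allclose(
            t1["fold_change"], t2.loc[t1.index, "fold_change"], atol=1e-12
        )

    def test_estimator_api_fitted_attributes(self):
        rng = np.random.default_rng(5)
        X = rng.normal(8, 1, size=(6, 12))  # arrays x probes
        y = np.array(["ALK_NEG"] * 3 + ["ALK_POS"] * 3)
        est = WelchDifferentialExpression(alpha=0.1).fit(X, y)
        assert est.classes_ == ("ALK_NEG", "ALK_POS")
        assert len(est.results_) == 12
        assert est.n_significant_ == int(est.results_["significant"].sum())
        params = est.get_params()
        assert params["alpha"] == 0.1
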