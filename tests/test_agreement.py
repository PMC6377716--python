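import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esovol import (
    PairedMeasurements,
    abs_pct_diff_from_mean,
    bland_altman,
    bland_altman_plot,
    compare_icc_fisher,
    icc,
)
from esovol.errors import SampleSizeError, UndefinedStatisticError, ValidationError

HAND_DATA = PairedMeasurements.from_arrays([1.0, 2.0, 3.0, 4.0, 6.0], [2.0, 1.0, 4.0, 5.0, 8.0])


def brute_force_icc(v1, v2, form):
    """Independent oracle: ANOVA sums of squares by explicit enumeration,
    then the single-measures Shrout-Fleiss estimator for each form."""
    x = [[a, b] for a, b in zip(v1, v2)]
    n, k = len(x), 2
    grand = sum(sum(row) for row in x) / (n * k)
    row_means = [sum(row) / k for row in x]
    col_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ss_total = sum((x[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    msw = (ss_total - ss_rows) / (n * (k - 1))
    if form == "oneway":
        return (msr - msw) / (msr + (k - 1) * msw)
    if form == "twoway_consistency":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    @pytest.mark.parametrize("form", ["oneway", "twoway_agreement", "twoway_consistency"])
    def test_matches_anova_brute_force(self, form):
        v1, v2 = HAND_DATA.arrays()
        expected = brute_force_icc(v1, v2, form)
        assert icc(HAND_DATA, form=form).value == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("form", ["oneway", "twoway_agreement", "twoway_consistency"])
    def test_perfect_agreement_gives_one(self, form):
        p = PairedMeasurements.from_arrays([1.0, 5.0, 9.0], [1.0, 5.0, 9.0])
        assert icc(p, form=form).value == pytest.approx(1.0)

    def test_zero_variance_is_undefined(self):
        p = PairedMeasurements.from_arrays([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        with pytest.raises(UndefinedStatisticError):
            icc(p)

    def test_consistency_shift_invariant_agreement_not(self):
        v1, v2 = HAND_DATA.arrays()
        shifted = PairedMeasurements.from_arrays(v1, v2 + 10.0)
        c0 = icc(HAND_DATA, form="twoway_consistency").value
        c1 = icc(shifted, form="twoway_consistency").value
        assert c1 == pytest.approx(c0, abs=1e-12)
        a0 = icc(HAND_DATA, form="twoway_agreement").value
        a1 = icc(shifted, form="twoway_agreement").value
        assert a1 < a0  # systematic offset strictly degrades absolute agreement

    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(0, 100)), min_size=4, max_size=20))
    @settings(deadline=None, max_examples=60)
    def test_agreement_at_most_consistency_at_most_one(self, pairs):
        v1 = np.array([a for a, _ in pairs])
        v2 = np.array([b for _, b in pairs])
        p = PairedMeasurements.from_arrays(v1, v2)
        try:
            a = icc(p, form="twoway_agreement").value
            c = icc(p, form="twoway_consistency").value
        except UndefinedStatisticError:
            return
        assert a <= 1.0 + 1e-12 and c <= 1.0 + 1e-12
        # absolute agreement can only be penalized relative to consistency
        # when the rater variance component is nonnegative (MSC >= MSE);
        # otherwise the agreement denominator shrinks and the order flips
        n = len(v1)
        grand = np.r_[v1, v2].mean()
        msc = n * (((v1.mean() - grand) ** 2) + ((v2.mean() - grand) ** 2))
        mse = (((v1 - v2) - (v1 - v2).mean()) ** 2).sum() / (2 * (n - 1))
        if msc >= mse and c >= 0:
            assert a <= c + 1e-9

    def test_matches_pingouin_estimates_and_ci(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        v1, v2 = HAND_DATA.arrays()
        df = pd.DataFrame({
            "targets": list(range(5)) * 2,
            "raters": ["a"] * 5 + ["b"] * 5,
            "scores": np.r_[v1, v2],
        })
        ref = pg.intraclass_corr(df, "targets", "raters", "scores").set_index("Type")
        for form, code in [("oneway", "ICC(1,1)"), ("twoway_agreement", "ICC(A,1)"),
                           ("twoway_consistency", "ICC(C,1)")]:
            r = icc(HAND_DATA, form=form)
            assert r.value == pytest.approx(ref.loc[code, "ICC"], abs=1e-10)
            # pingouin rounds its CI95 to 2 d.p.
            np.testing.assert_allclose(r.ci, ref.loc[code, "CI95"], atol=5.1e-3)


class TestFisherComparison:
    def test_equal_correlations(self):
        z, p = compare_icc_fisher(0.7, 30, 0.7, 50)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_closed_form_by_hand(self):
        z, _ = compare_icc_fisher(0.5, 50, 0.0, 50)
        assert z == pytest.approx(math.atanh(0.5) / math.sqrt(2 / 47), rel=1e-12)

    def test_antisymmetric_in_arguments(self):
        z1, p1 = compare_icc_fisher(0.86, 46, 0.56, 46)
        z2, p2 = compare_icc_fisher(0.56, 46, 0.86, 46)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_inputs(self):
        with pytest.raises(UndefinedStatisticError):
            compare_icc_fisher(1.0, 10, 0.5, 10)
        with pytest.raises(SampleSizeError):
            compare_icc_fisher(0.5, 3, 0.5, 10)


class TestBlandAltman:
    def test_identical_pairs(self):
        p = PairedMeasurements.from_arrays([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        ba = bland_altman(p)
        assert ba.mean_diff == 0.0 and ba.width == 0.0

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=30))
    @settings(deadline=None, max_examples=60)
    def test_width_is_392_times_sample_sd(self, diffs):
        v2 = [50.0 + abs(d) for d in diffs]  # keep values nonnegative
        v1 = [b + d for b, d in zip(v2, diffs)]
        ba = bland_altman(PairedMeasurements.from_arrays(v1, v2))
        assert ba.width == pytest.approx(3.92 * np.std(diffs, ddof=1), rel=1e-9, abs=1e-9)
        assert ba.width == pytest.approx(ba.loa_upper - ba.loa_lower, rel=1e-9, abs=1e-9)

    def test_single_pair_rejected(self):
        with pytest.raises(SampleSizeError):
            bland_altman(PairedMeasurements.from_arrays([1.0], [2.0]))


class TestAbsPctDiff:
    def test_equal_values_give_zero(self):
        p = PairedMeasurements.from_arrays([5.0, 7.0], [5.0, 7.0])
        assert abs_pct_diff_from_mean(p)[0] == 0.0

    def test_single_item_arithmetic(self):
        p = PairedMeasurements.from_arrays([40.0], [60.0])
        assert abs_pct_diff_from_mean(p)[0] == pytest.approx(20.0)

    @given(
        st.lists(st.tuples(st.floats(0.1, 100), st.floats(0.1, 100)), min_size=1, max_size=20),
        st.floats(0.1, 50),
    )
    @settings(deadline=None, max_examples=60)
    def test_symmetric_and_scale_invariant(self, pairs, c):
        v1 = np.array([a for a, _ in pairs])
        v2 = np.array([b for _, b in pairs])
        m, _ = abs_pct_diff_from_mean(PairedMeasurements.from_arrays(v1, v2))
        m_swap, _ = abs_pct_diff_from_mean(PairedMeasurements.from_arrays(v2, v1))
        m_scaled, _ = abs_pct_diff_from_mean(PairedMeasurements.from_arrays(c * v1, c * v2))
        assert m_swap == pytest.approx(m, rel=1e-9, abs=1e-12)
        assert m_scaled == pytest.approx(m, rel=1e-6, abs=1e-9)

    def test_item_with_both_zero_named(self):
        p = PairedMeasurements([("p1", 1.0, 2.0), ("p2", 0.0, 0.0)])
        with pytest.raises(UndefinedStatisticError, match="p2"):
            abs_pct_diff_from_mean(p)


class TestBlandAltmanPlot:
    def test_plot_written_and_consistent_with_statistics(self, tmp_path):
        p = PairedMeasurements.from_arrays([10.0, 20.0, 30.0, 44.0], [12.0, 18.0, 33.0, 40.0])
        out = tmp_path / "ba.png"
        means, diffs, ba = bland_altman_plot(p, out)
        assert out.exists() and out.stat().st_size > 0
        ref = bland_altman(p)
        assert ba.mean_diff == ref.mean_diff and ba.width == ref.width
        v1, v2 = p.arrays()
        np.testing.assert_allclose(means, (v1 + v2) / 2)
        np.testing.assert_allclose(diffs, v1 - v2)

    def test_identical_pairs_plot_on_zero_line(self, tmp_path):
        p = PairedMeasurements.from_arrays([5.0, 9.0, 13.0], [5.0, 9.0, 13.0])
        _, diffs, _ = bland_altman_plot(p, tmp_path / "zero.png")
        assert np.all(diffs == 0.0)


def test_paired_measurements_validation():
    with pytest.raises(ValidationError):
        PairedMeasurements([("a", 1.0, 2.0), ("a", 3.0, 4.0)])  # duplicate id
    with pytest.raises(ValidationError):
        PairedMeasurements([("a", -1.0, 2.0)])
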