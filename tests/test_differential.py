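import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from miredit.differential import (
    abundance_residuals,
    bh_adjust,
    differential_editing,
    median_of_ratios_normalize,
    spearman_correlation,
    welch_t_test,
)
from miredit.editing_sites import SampleEditingMatrix


def welch_oracle(x, y):
    """Textbook Welch statistic and Welch-Satterthwaite df, from scratch."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


class TestWelch:
    def test_textbook_example(self):
        res = welch_t_test([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        assert res.t == pytest.approx(-3.674, abs=1e-3)
        assert res.df == pytest.approx(4.0, abs=1e-9)
        assert res.p == pytest.approx(0.0213, abs=5e-4)

    def test_identical_groups_zero_variance(self):
        res = welch_t_test([0.5, 0.5], [0.5, 0.5])
        assert res.t == 0.0 and res.p == 1.0 and res.testable

    def test_zero_variance_unequal_means_untestable(self):
        res = welch_t_test([0.2, 0.2], [0.8, 0.8])
        assert not res.testable and math.isnan(res.p)

    def test_group_swap_flips_t_keeps_p(self):
        x, y = [0.1, 0.25, 0.33], [0.44, 0.5, 0.61, 0.7]
        a, b = welch_t_test(x, y), welch_t_test(y, x)
        assert a.t == pytest.approx(-b.t) and a.p == pytest.approx(b.p)

    def test_missing_values_dropped(self):
        res = welch_t_test([0.1, 0.2, np.nan], [0.4, np.nan, 0.6])
        ref = welch_t_test([0.1, 0.2], [0.4, 0.6])
        assert res.t == pytest.approx(ref.t)

    def test_fewer_than_two_per_group_untestable(self):
        assert not welch_t_test([0.1], [0.4, 0.5]).testable

    @given(
        st.lists(st.floats(0.01, 0.99), min_size=2, max_size=10),
        st.lists(st.floats(0.01, 0.99), min_size=2, max_size=10),
    )
    def test_matches_formula_oracle(self, x, y):
        if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
            return
        t, df, p = welch_oracle(x, y)
        res = welch_t_test(x, y)
        assert res.t == pytest.approx(t, abs=1e-9)
        assert res.df == pytest.approx(df, abs=1e-9)
        assert res.p == pytest.approx(p, abs=1e-9)


class TestBH:
    def test_hand_stepped_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_hand_stepped_mixed(self):
        # step-up: sorted p * m/rank, then running minimum from the top:
        # sorted (.005,.03,.04,.9) -> (.02,.06,.05333,.9) -> min-from-top
        # (.02,.05333,.05333,.9), mapped back to input order
        np.testing.assert_allclose(
            bh_adjust([0.005, 0.04, 0.03, 0.9]), [0.02, 0.16 / 3, 0.16 / 3, 0.9]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.123]), [0.123])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan, 0.5]):
            with pytest.raises(ValueError):
                bh_adjust(bad)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    def test_permutation_stable_and_bounded(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj <= 1.0 + 1e-12) and np.all(adj >= np.asarray(ps) - 1e-12)
        perm = np.random.default_rng(0).permutation(len(ps))
        np.testing.assert_allclose(np.asarray(adj)[perm], bh_adjust(np.asarray(ps)[perm]))

    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=30))
    def test_monotone_on_sorted_input(self, ps):
        adj = bh_adjust(np.sort(ps))
        assert np.all(np.diff(adj) >= -1e-12)


class TestDifferentialEditing:
    def _matrix(self, levels, design):
        df = pd.DataFrame(levels, columns=list(design["sample_id"]))
        df.index = [f"m{i}-3p:6" for i in range(len(df))]
        return df

    def test_single_site_bh_equals_raw(self, two_group_design):
        levels = self._matrix([[0.1, 0.2, 0.3, 0.5, 0.6, 0.7]], two_group_design)
        out = differential_editing(levels, two_group_design)
        assert out.p_bh.iloc[0] == pytest.approx(out.p_raw.iloc[0])

    def test_untestable_site_excluded_from_family(self, two_group_design):
        levels = self._matrix(
            [
                [0.1, 0.2, 0.3, 0.5, 0.6, 0.7],
                [0.2, 0.2, 0.2, 0.8, 0.8, 0.8],  # zero variance, unequal means
            ],
            two_group_design,
        )
        out = differential_editing(levels, two_group_design)
        assert not out.testable.iloc[1] and math.isnan(out.p_bh.iloc[1])
        # BH family has size 1, so the testable site keeps its raw p
        assert out.p_bh.iloc[0] == pytest.approx(out.p_raw.iloc[0])

    def test_group_means_reported(self, two_group_design):
        levels = self._matrix([[0.1, 0.2, 0.3, 0.5, 0.6, 0.7]], two_group_design)
        out = differential_editing(levels, two_group_design)
        assert out["mean_control"].iloc[0] == pytest.approx(0.2)
        assert out["mean_case"].iloc[0] == pytest.approx(0.6)

    def test_design_mismatch_rejected(self, two_group_design):
        levels = self._matrix([[0.1, 0.2, 0.3, 0.5, 0.6, 0.7]], two_group_design)
        bad = two_group_design.copy()
        bad.loc[0, "sample_id"] = "not-in-matrix"
        with pytest.raises(ValueError, match="absent"):
            differential_editing(levels, bad)

    def test_three_groups_rejected(self, two_group_design):
        bad = two_group_design.copy()
        bad.loc[0, "group"] = "third"
        levels = self._matrix([[0.1, 0.2, 0.3, 0.5, 0.6, 0.7]], two_group_design)
        with pytest.raises(ValueError, match="two groups"):
            differential_editing(levels, bad)


class TestAbundanceResiduals:
    def test_collinear_input_perfect_fit(self):
        total = np.array([100.0, 200.0, 400.0, 800.0])
        report = abundance_residuals(0.5 * total, total, transform="linear")
        np.testing.assert_allclose(report.table.residual, 0.0, atol=1e-9)
        assert report.pearson_r == pytest.approx(1.0)

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(1)
        total = rng.integers(100, 10000, size=12).astype(float)
        edited = 0.6 * total + rng.normal(0, 20, size=12)
        report = abundance_residuals(edited, total, transform="linear")
        assert abs(report.table.residual.sum()) <= 1e-9 * np.abs(
            report.table.edited
        ).sum()

    def test_constant_total_degenerate(self):
        report = abundance_residuals(
            [1.0, 2.0, 3.0], [5.0, 5.0, 5.0], transform="linear"
        )
        assert report.degenerate and math.isnan(report.pearson_r)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3"):
            abundance_residuals([1.0, 2.0], [1.0, 2.0])

    def test_offset_group_sits_above_the_line(self):
        # samples whose edited abundance exceeds what total abundance
        # predicts have positive residuals
        rng = np.random.default_rng(2)
        total = rng.uniform(1000, 5000, size=16)
        edited = 0.5 * total
        edited[:8] *= 1.8  # planted offset group
        report = abundance_residuals(edited, total, transform="linear")
        assert (report.table.residual[:8] > 0).all()


class TestMedianOfRatios:
    def test_hand_evaluated_example(self):
        counts = pd.DataFrame({"s1": [2, 4, 6], "s2": [4, 8, 12]})
        _, factors = median_of_ratios_normalize(counts)
        np.testing.assert_allclose(factors, [1 / math.sqrt(2), math.sqrt(2)], rtol=1e-9)

    def test_identical_columns_unit_factors(self):
        counts = pd.DataFrame({"s1": [5, 9, 2], "s2": [5, 9, 2]})
        _, factors = median_of_ratios_normalize(counts)
        np.testing.assert_allclose(factors, [1.0, 1.0])

    def test_scale_equivariance_of_factor_ratios(self):
        # scaling one library by c scales its size factor, relative to the
        # others, by exactly c (absolute factors shift because the
        # geometric-mean reference includes the scaled sample)
        counts = pd.DataFrame({"s1": [5, 9, 2], "s2": [7, 3, 11]})
        _, f1 = median_of_ratios_normalize(counts)
        scaled = counts.copy()
        scaled["s2"] = scaled["s2"] * 4
        _, f2 = median_of_ratios_normalize(scaled)
        before = f1["s2"] / f1["s1"]
        after = f2["s2"] / f2["s1"]
        assert after / before == pytest.approx(4.0, rel=1e-9)

    def test_no_all_positive_row_rejected(self):
        counts = pd.DataFrame({"s1": [0, 4], "s2": [4, 0]})
        with pytest.raises(ValueError, match="all-positive"):
            median_of_ratios_normalize(counts)


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman_correlation(x, np.exp(x)) == pytest.approx(1.0)

    def test_reversed_order_gives_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman_correlation(x, -x) == pytest.approx(-1.0)

    def test_ties_match_midrank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0])
        y = np.array([3.0, 1.0, 4.0, 4.0, 2.0, 6.0, 5.0])
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman_correlation(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_undefined(self):
        assert math.isnan(spearman_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))
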