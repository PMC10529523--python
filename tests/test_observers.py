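"""Variance percentage, composition categories, match rates, chi-squared."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thyrotex.observers import (
    DEFAULT_SCHEME,
    CompositionScheme,
    all_observer_match_percentage,
    chi_squared_variance_test,
    classification_match_percentage,
    composition_category,
    render_truncated,
    variance_percentage,
    variance_table,
)


def table_from(rows, columns=("P1", "P2", "P3", "DSS")):
    df = pd.DataFrame(rows, columns=list(columns))
    df.index = pd.RangeIndex(1, len(df) + 1, name="nodule_id")
    return df


class TestVariancePercentage:
    @pytest.mark.parametrize(
        "obs1,obs2,expected",
        [(10, 8, 20.0), (5, 14, -180.0), (70, 22, pytest.approx(68.5714, abs=1e-3)),
         (45, 1, pytest.approx(97.7778, abs=1e-3)), (50, 50, 0.0), (0, 0, 0.0)],
    )
    def test_known_values(self, obs1, obs2, expected):
        assert variance_percentage(obs1, obs2) == expected

    def test_undefined_zero_denominator_is_na(self):
        assert math.isnan(variance_percentage(0, 22))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            variance_percentage(-1, 10)
        with pytest.raises(ValueError):
            variance_percentage(10, 101)

    @settings(max_examples=200, deadline=None)
    @given(
        a=st.floats(0.1, 100),
        b=st.floats(0, 100),
    )
    def test_sign_follows_deviation(self, a, b):
        vp = variance_percentage(a, b)
        assert math.copysign(1, vp) == math.copysign(1, a - b) or vp == 0
        assert (vp == 0) == (a == b)


class TestVarianceTable:
    def test_reference_subtracted_per_row(self):
        table = table_from([[50, 25, 25, 25]])
        vt = variance_table(table, "DSS")
        assert vt.loc[1, "P1"] == 50.0
        assert vt.loc[1, "P2"] == 0.0

    def test_identical_observers_give_zero(self):
        table = table_from([[30, 30, 30, 30], [5, 5, 5, 5]])
        assert (variance_table(table, "DSS").to_numpy() == 0).all()

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            variance_table(table_from([[1, 2, 3, 4]]), "XYZ")

    @pytest.mark.parametrize(
        "value,decimals,expected",
        [(97.7778, 1, 97.7), (68.5714, 2, 68.57), (71.5789, 1, 71.5), (-6.6667, 1, -6.6)],
    )
    def test_printed_style_truncation(self, value, decimals, expected):
        assert render_truncated(value, decimals) == pytest.approx(expected)


class TestCompositionCategories:
    @pytest.mark.parametrize(
        "pct,name",
        [(0, "solid"), (9.9, "solid"), (10, "predominantly solid"),
         (50, "predominantly cystic"), (89.9, "predominantly cystic"),
         (90, "cystic"), (100, "cystic")],
    )
    def test_default_scheme_boundaries(self, pct, name):
        assert composition_category(pct) == name

    def test_breakpoints_validated(self):
        with pytest.raises(ValueError):
            CompositionScheme(breakpoints=(50.0, 10.0), names=("a", "b", "c"))


class TestMatchPercentages:
    def test_identical_columns_match_fully(self):
        table = table_from([[10, 10, 10, 10], [80, 80, 80, 80]])
        assert classification_match_percentage(table, "P1", "DSS") == 100.0
        res = all_observer_match_percentage(table, ["P1", "P2", "P3"], "DSS")
        assert res["all_agree_pct"] == 100.0
        assert res["mean_observer_pct"] == 100.0

    def test_disjoint_categories_never_match(self):
        table = table_from([[5, 5, 5, 95], [20, 20, 20, 95]])
        assert classification_match_percentage(table, "P1", "DSS") == 0.0
        assert all_observer_match_percentage(table, ["P1", "P2"], "DSS")["all_agree_pct"] == 0.0

    def test_fractional_match_counts_rows(self):
        rows = [[5, 5, 5, 5]] * 15 + [[5, 5, 5, 95]] * 11
        assert classification_match_percentage(table_from(rows), "P1", "DSS") == pytest.approx(
            100 * 15 / 26
        )

    def test_row_order_invariance_and_range(self):
        rng = np.random.default_rng(1)
        rows = rng.uniform(0, 100, size=(30, 4))
        t1 = table_from(rows)
        t2 = table_from(rows[::-1])
        p1 = classification_match_percentage(t1, "P1", "DSS")
        p2 = classification_match_percentage(t2, "P1", "DSS")
        assert p1 == p2
        assert 0.0 <= p1 <= 100.0


class TestChiSquared:
    def test_identical_distributions_give_zero(self):
        table = table_from([[5, 5, 5, 5], [60, 60, 60, 60], [95, 95, 95, 95]])
        res = chi_squared_variance_test(table)
        assert res["statistic"] == 0.0
        assert res["p_value"] == 1.0

    def test_matches_hand_computed_pearson(self):
        # two observers, two realized categories, counts [[10,0],[0,10]]
        table = table_from(
            [[5.0, 95.0]] * 10, columns=("A", "B")
        )
        res = chi_squared_variance_test(table, observers=["A", "B"])
        assert res["statistic"] == pytest.approx(20.0)
        assert res["df"] == 1
        assert res["p_value"] < 0.001

    def test_degenerate_single_category(self):
        table = table_from([[5, 5, 5, 5]] * 4)
        with pytest.warns(UserWarning):
            res = chi_squared_variance_test(table)
        assert res == {"statistic": 0.0, "df": 0, "p_value": 1.0}

    def test_statistic_non_negative(self):
        rng = np.random.default_rng(8)
        table = table_from(rng.uniform(0, 100, size=(26, 4)))
        assert chi_squared_variance_test(table)["statistic"] >= 0.0
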