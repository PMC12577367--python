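"""Timing statistics, exact tests against enumeration oracles, qPCR closed forms."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

import abscission as ab
from abscission.exceptions import DataError


class TestMidbodyLifetime:
    def test_formation_to_severing_subtraction(self):
        rec = {"t_midbody_form": 0.0, "t_midbody_sever": 130.0}
        assert ab.midbody_lifetime(rec) == 130.0

    def test_unobserved_severing_is_censored(self):
        assert ab.midbody_lifetime({"t_midbody_form": 10.0, "t_midbody_sever": np.nan}) is None

    def test_severing_before_formation_is_a_data_error(self):
        with pytest.raises(DataError):
            ab.midbody_lifetime({"t_midbody_form": 50.0, "t_midbody_sever": 40.0})


class TestCompletionFractions:
    def test_all_observed_curve_reaches_one(self):
        curve = ab.cumulative_fraction([10.0, 20.0, 30.0], horizon_min=60.0)
        assert curve.loc[curve["t_min"] >= 30.0, "fraction"].eq(1.0).all()

    def test_censored_cells_stay_in_the_denominator(self):
        curve = ab.cumulative_fraction([10.0, None, None], horizon_min=60.0)
        assert curve["fraction"].max() == pytest.approx(1 / 3)

    def test_curve_is_non_decreasing_for_arbitrary_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            times = [float(t) if rng.random() > 0.3 else None for t in rng.uniform(0, 100, 12)]
            curve = ab.cumulative_fraction(times, horizon_min=80.0)
            assert (np.diff(curve["fraction"]) >= 0).all()

    def test_scalar_fraction_consistent_with_curve_at_horizon(self):
        times = [50.0, 70.0, None, 20.0, 61.0]
        curve = ab.cumulative_fraction(times, horizon_min=60.0)
        assert curve["fraction"].iloc[-1] == ab.fraction_completed_by(times, 60.0)

    def test_examples(self):
        assert ab.fraction_completed_by([50.0, 70.0, None], 60.0) == pytest.approx(1 / 3)
        assert ab.fraction_completed_by([None, None], 60.0) == 0.0
        assert ab.fraction_completed_by([50.0, 70.0, None], math.inf) == pytest.approx(2 / 3)
        with pytest.raises(DataError):
            ab.fraction_completed_by([], 60.0)


def mann_whitney_enumeration_oracle(x, y):
    """Full-permutation exact two-sided p over all assignments of the pooled sample."""
    pooled = sorted(list(x) + list(y))
    n_x = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n_x):
        chosen = set(comb)
        u = sum(
            1
            for i in comb
            for j in range(len(pooled))
            if j not in chosen and pooled[i] > pooled[j]
        )
        us.append(u)
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return u_obs, min(1.0, p)


class TestMannWhitney:
    def test_textbook_example_exact(self):
        res = ab.mann_whitney([1, 2], [3, 4])
        assert res["U"] == 0
        assert res["p_two_sided"] == pytest.approx(2 / 6)
        assert res["method"] == "exact"

    def test_identical_samples_give_p_one(self):
        res = ab.mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["p_two_sided"] == pytest.approx(1.0)

    def test_exact_branch_matches_enumeration_for_small_samples(self):
        rng = np.random.default_rng(1)
        for n_x in range(1, 5):
            for n_y in range(1, 5):
                values = rng.permutation(np.arange(1.0, n_x + n_y + 1))
                x, y = list(values[:n_x]), list(values[n_x:])
                res = ab.mann_whitney(x, y)
                u_oracle, p_oracle = mann_whitney_enumeration_oracle(x, y)
                assert res["U"] == u_oracle
                assert res["p_two_sided"] == pytest.approx(p_oracle, abs=1e-12)

    def test_empty_sample_is_an_error(self):
        with pytest.raises(DataError):
            ab.mann_whitney([], [1.0])


def fisher_rational_oracle(a, b, c, d):
    """Exact-rational two-sided Fisher p by direct table enumeration."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if n == 0 or row1 in (0, n) or col1 in (0, n):
        return Fraction(1)

    def pmf(k):
        return (
            Fraction(math.comb(col1, k) * math.comb(n - col1, row1 - k), math.comb(n, row1))
        )

    p_obs = pmf(a)
    total = Fraction(0)
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = pmf(k)
        if p <= p_obs + p_obs / 10**7:
            total += p
    return min(Fraction(1), total)


class TestFishersExact:
    def test_perfect_diagonal_table(self):
        assert ab.fishers_exact([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_zero_margin_gives_p_one(self):
        assert ab.fishers_exact([[0, 0], [3, 4]]) == 1.0
        assert ab.fishers_exact([[0, 3], [0, 4]]) == 1.0

    def test_negative_entries_are_an_error(self):
        with pytest.raises(DataError):
            ab.fishers_exact([[1, -2], [3, 4]])

    def test_matches_rational_enumeration_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(60):
            a, b, c, d = (int(v) for v in rng.integers(0, 7, 4))
            mine = ab.fishers_exact([[a, b], [c, d]])
            assert mine == pytest.approx(float(fisher_rational_oracle(a, b, c, d)), abs=1e-10)

    def test_agrees_with_scipy_reference(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            a, b, c, d = (int(v) for v in rng.integers(0, 10, 4))
            assert ab.fishers_exact([[a, b], [c, d]]) == pytest.approx(
                sps.fisher_exact([[a, b], [c, d]])[1], abs=1e-10
            )


class TestBoxSummary:
    def test_one_to_hundred_quartiles_by_linear_interpolation(self):
        s = ab.box_summary(range(1, 101))
        assert s.median == 50.5
        assert s.q1 == 25.75
        assert s.q3 == 75.25
        assert s.outliers.size == 0
        assert s.whisker_lo == 1 and s.whisker_hi == 100

    def test_single_value_gives_degenerate_box(self):
        s = ab.box_summary([7.0])
        assert s.median == s.q1 == s.q3 == s.whisker_lo == s.whisker_hi == 7.0

    def test_extreme_point_becomes_outlier_without_moving_the_whisker_past_the_fence(self):
        base = list(range(1, 21))
        s0 = ab.box_summary(base)
        s1 = ab.box_summary(base + [1000.0])
        assert 1000.0 in s1.outliers
        assert s1.whisker_hi <= s1.q3 + 1.5 * (s1.q3 - s1.q1)
        assert s0.whisker_hi == 20.0


class TestQpcr:
    def _table(self, delta_control, delta_sample):
        rows = []
        for rep in range(3):
            rows.append({"sample": "ctrl", "ct_target": 20.0 + delta_control,
                         "ct_reference": 20.0, "is_control": True, "replicate": rep})
            rows.append({"sample": "treated", "ct_target": 20.0 + delta_sample,
                         "ct_reference": 20.0, "is_control": False, "replicate": rep})
        return pd.DataFrame(rows)

    def test_equal_delta_ct_normalizes_to_one(self):
        out = ab.qpcr_relative_expression(self._table(1.3, 1.3)).set_index("sample")
        assert out.loc["treated", "re_normalized"] == pytest.approx(1.0)

    def test_one_cycle_difference_halves_expression(self):
        out = ab.qpcr_relative_expression(self._table(0.0, 1.0)).set_index("sample")
        assert out.loc["treated", "re_normalized"] == pytest.approx(0.5)

    def test_two_point_three_cycles_give_eighty_percent_reduction(self):
        out = ab.qpcr_relative_expression(self._table(0.0, math.log2(5.0))).set_index("sample")
        assert out.loc["treated", "re_normalized"] == pytest.approx(0.2, abs=1e-9)

    def test_invariant_under_constant_ct_shift(self):
        t1 = self._table(0.0, 2.0)
        t2 = t1.copy()
        t2[["ct_target", "ct_reference"]] += 5.0
        o1 = ab.qpcr_relative_expression(t1)["re_normalized"]
        o2 = ab.qpcr_relative_expression(t2)["re_normalized"]
        assert o1.tolist() == pytest.approx(o2.tolist())

    def test_missing_control_is_an_error(self):
        table = self._table(0.0, 1.0)
        table["is_control"] = False
        with pytest.raises(DataError):
            ab.qpcr_relative_expression(table)


class TestPrimerEfficiency:
    def test_ideal_slope_gives_hundred_percent(self):
        x = np.array([0.0, -1.0, -2.0, -3.0])
        y = 20.0 - 3.3219 * x
        res = ab.primer_efficiency(x, y)
        assert res["efficiency"] == pytest.approx(1.0, abs=1e-3)
        assert res["passes"]

    def test_shallow_slope_fails_the_ninety_percent_rule(self):
        x = np.array([0.0, -1.0, -2.0, -3.0])
        y = 20.0 - 3.9 * x
        res = ab.primer_efficiency(x, y)
        assert res["efficiency"] == pytest.approx(0.805, abs=0.005)
        assert not res["passes"]

    def test_two_points_are_an_error(self):
        with pytest.raises(DataError):
            ab.primer_efficiency([0.0, -1.0], [20.0, 23.3])


class TestFrequencyTable:
    def test_binucleation_proportion(self):
        df = pd.DataFrame(
            {"condition": ["icrf"] * 10, "binucleate": [True, True] + [False] * 8}
        )
        out = ab.frequency_table(df, "binucleate")
        assert out.loc[0, "proportion"] == pytest.approx(0.2)
        assert out.loc[0, "count"] == 2 and out.loc[0, "n"] == 10

    def test_counts_feed_fishers_exact(self):
        df = pd.DataFrame(
            {
                "condition": ["a"] * 10 + ["b"] * 10,
                "binucleate": [True] * 5 + [False] * 5 + [True] * 1 + [False] * 9,
            }
        )
        out = ab.frequency_table(df, "binucleate").set_index("condition")
        table = [
            [int(out.loc["a", "count"]), int(out.loc["a", "n"] - out.loc["a", "count"])],
            [int(out.loc["b", "count"]), int(out.loc["b", "n"] - out.loc["b", "count"])],
        ]
        assert 0.0 < ab.fishers_exact(table) <= 1.0

    def test_callable_predicate(self):
        df = pd.DataFrame({"condition": ["a", "a", "a"], "t_abscission": [10.0, 70.0, np.nan]})
        out = ab.frequency_table(df, lambda r: r["t_abscission"] <= 60.0)
        assert out.loc[0, "proportion"] == pytest.approx(1 / 3)


class TestCohortRecovery:
    def test_synthetic_condition_medians_recovered_within_two_minutes(self):
        # two arms with true abscission-time medians 16 and 24 min, n = 100
        df = ab.generate_event_table(
            100,
            [
                ("control", {"t_abscission": ("lognormal", math.log(16.0), 0.35)}),
                ("stressed", {"t_abscission": ("lognormal", math.log(24.0), 0.35)}),
            ],
            seed=11,
        )
        med = df.groupby("condition")["t_abscission"].median()
        assert med["control"] == pytest.approx(16.0, abs=2.0)
        assert med["stressed"] == pytest.approx(24.0, abs=2.0)
        res = ab.mann_whitney(
            df.loc[df["condition"] == "control", "t_abscission"],
            df.loc[df["condition"] == "stressed", "t_abscission"],
        )
        assert res["p_two_sided"] < 0.001
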