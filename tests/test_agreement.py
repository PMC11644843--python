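"""Agreement-statistics tests: confusion metrics, PPV identity, CCC, kappa."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ethoval import (
    ConfusionCounts,
    cohen_kappa,
    confusion,
    evaluate,
    lin_ccc,
    merge_sources,
    ppv,
    prevalence,
    r_squared,
    rmse,
    se_sp_ac,
    spearman,
)
from ethoval.agreement import InsufficientDataError

from conftest import make_minutes


class TestConfusion:
    def test_perfect_prediction(self):
        c = confusion([1, 0, 1, 0], [1, 0, 1, 0])
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)

    def test_complement_prediction(self):
        c = confusion([0, 1, 0, 1], [1, 0, 1, 0])
        assert c.tp == 0 and c.tn == 0 and c.fp == 2 and c.fn == 2

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(1)
        pred = rng.integers(0, 2, 1000)
        gold = rng.integers(0, 2, 1000)
        c = confusion(pred, gold)
        tally = {(p, g): int(np.sum((pred == p) & (gold == g))) for p in (0, 1) for g in (0, 1)}
        assert c.tp == tally[(1, 1)]
        assert c.fp == tally[(1, 0)]
        assert c.fn == tally[(0, 1)]
        assert c.tn == tally[(0, 0)]

    def test_no_overlap_raises(self):
        with pytest.raises(InsufficientDataError):
            confusion([np.nan, np.nan], [1.0, 0.0])


class TestSeSpAc:
    @pytest.mark.parametrize(
        "se, sp, ac",
        [(0.837, 0.989, 0.913), (0.387, 0.993, 0.690)],
    )
    def test_balanced_accuracy_from_fractions(self, se, sp, ac):
        _, _, got = se_sp_ac(se, sp)
        assert got == pytest.approx(ac, abs=5e-4)

    def test_from_counts(self):
        c = ConfusionCounts(tp=8, fp=1, fn=2, tn=9)
        se, sp, ac = se_sp_ac(c)
        assert se == 0.8 and sp == 0.9 and ac == pytest.approx(0.85)

    def test_empty_truth_class_is_nan_not_zero(self):
        se, sp, ac = se_sp_ac(ConfusionCounts(tp=0, fp=0, fn=0, tn=10))
        assert math.isnan(se) and math.isnan(ac) and sp == 1.0

    def test_perfect_prediction_all_ones(self):
        se, sp, ac = se_sp_ac(ConfusionCounts(tp=5, fp=0, fn=0, tn=5))
        assert se == sp == ac == 1.0


class TestPpv:
    def test_perfect_tests(self):
        assert ppv(1.0, 1.0, 0.3) == 1.0

    def test_uninformative_test(self):
        assert ppv(0.5, 0.5, 0.5) == pytest.approx(0.5)

    def test_published_operating_point(self):
        # SE 83.0%, SP 98.9%, prevalence 12% -> PPV ~ 91.1% (prints as 91.2
        # with unrounded inputs)
        assert ppv(0.830, 0.989, 0.12) == pytest.approx(0.9114, abs=5e-4)

    def test_count_identity_on_random_matrices(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 500, size=(2000, 4))
        for tp, fp, fn, tn in counts:
            if tp + fp == 0 or tp + fn == 0 or tn + fp == 0:
                continue
            c = ConfusionCounts(int(tp), int(fp), int(fn), int(tn))
            se, sp, _ = se_sp_ac(c)
            assert ppv(se, sp, prevalence(c)) == pytest.approx(
                tp / (tp + fp), abs=1e-12
            )

    def test_zero_denominator_is_nan(self):
        assert math.isnan(ppv(0.0, 1.0, 0.5))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ppv(1.2, 0.5, 0.5)


class TestLinCcc:
    def test_identity_series(self):
        assert lin_ccc([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_closed_form_shifted_line(self):
        assert lin_ccc([1, 2, 3], [2, 3, 4]) == pytest.approx(4 / 7)

    def test_anti_correlated_zero_mean(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert lin_ccc(x, -x) == pytest.approx(-1.0)

    def test_bounded_by_pearson_on_random_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            x = rng.normal(size=30)
            y = 0.5 * x + rng.normal(size=30) + rng.normal()
            c = lin_ccc(x, y)
            r = stats.pearsonr(x, y).statistic
            assert abs(c) <= abs(r) + 1e-12

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=50), rng.normal(size=50)
        perm = rng.permutation(50)
        assert lin_ccc(x, y) == pytest.approx(lin_ccc(x[perm], y[perm]))

    def test_constant_series_is_nan(self):
        assert math.isnan(lin_ccc([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]))

    def test_attains_one_only_for_identical_series(self):
        assert lin_ccc([1, 2, 3], [1, 2, 3.0001]) < 1.0


class TestOtherCoefficients:
    def test_spearman_monotone_nonlinear(self):
        x = np.linspace(0, 5, 20)
        assert spearman(x, np.exp(x)) == pytest.approx(1.0)

    def test_r_squared_and_rmse_identity(self):
        x = np.array([1.0, 2.0, 5.0])
        assert r_squared(x, x) == pytest.approx(1.0)
        assert rmse(x, x) == 0.0

    def test_rmse_direct_arithmetic(self):
        assert rmse([0.0, 10.0], [10.0, 0.0]) == 10.0

    def test_constant_input_correlations_are_nan(self):
        assert math.isnan(spearman([1, 1, 1], [1, 2, 3]))
        assert math.isnan(r_squared([1, 2, 3], [2, 2, 2]))


class TestCohenKappa:
    def test_identical_series(self):
        assert cohen_kappa([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0

    def test_hand_evaluated_two_by_two_table(self):
        # table (45, 5; 5, 45): p_o = 0.9, p_e = 0.5 -> kappa = 0.8
        a = [0] * 50 + [1] * 50
        b = [0] * 45 + [1] * 5 + [0] * 5 + [1] * 45
        assert cohen_kappa(a, b) == pytest.approx(0.8)

    def test_independent_labels_near_zero(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 2, 100_000)
        b = rng.integers(0, 2, 100_000)
        assert abs(cohen_kappa(a, b)) < 0.05

    def test_degenerate_marginals_are_nan(self):
        assert math.isnan(cohen_kappa([1, 1, 1], [1, 1, 1]))


class TestEvaluate:
    def test_perfect_sensor_has_perfect_metrics(self):
        labels = np.array([1, 0, 1, 1, 0, 0, 1, 0], dtype=float)
        merged = merge_sources(
            {"ivo": make_minutes(labels), "sensor": make_minutes(labels)}
        )
        row = evaluate(merged, gold="ivo").loc["sensor"]
        assert row["se"] == row["sp"] == row["ac"] == row["ppv"] == 1.0
        assert row["ccc"] == pytest.approx(1.0)
        assert row["n"] == 8

    def test_composition_identity_with_manual_calls(self):
        rng = np.random.default_rng(6)
        gold = rng.integers(0, 2, 500).astype(float)
        pred = gold.copy()
        flip = rng.random(500) < 0.1
        pred[flip] = 1 - pred[flip]
        merged = merge_sources(
            {"ivo": make_minutes(gold), "s": make_minutes(pred)}
        )
        row = evaluate(merged, gold="ivo").loc["s"]
        c = confusion(pred, gold)
        se, sp, ac = se_sp_ac(c)
        assert row["se"] == se and row["sp"] == sp and row["ac"] == ac
        assert row["ppv"] == pytest.approx(ppv(se, sp, prevalence(c)))
        assert row["ccc"] == pytest.approx(lin_ccc(pred, gold))
        assert row["r_s"] == pytest.approx(spearman(pred, gold))

    def test_ten_min_battery_reports_numeric_metrics(self):
        rng = np.random.default_rng(7)
        from ethoval import to_intervals

        gold = make_minutes(rng.integers(0, 2, 600).astype(float))
        noisy = make_minutes(
            np.clip(gold.labels + (rng.random(600) < 0.05), 0, 1)
        )
        merged = merge_sources(
            {"ivo": to_intervals(gold), "s": to_intervals(noisy)}
        )
        row = evaluate(merged, gold="ivo").loc["s"]
        assert 0 <= row["r2"] <= 1
        assert row["rmse"] >= 0
        assert row["n"] == 60
        assert math.isnan(row["se"])  # categorical battery not run at 10 min


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    tp=st.integers(0, 200),
    fp=st.integers(0, 200),
    fn=st.integers(0, 200),
    tn=st.integers(0, 200),
)
def test_ac_bounded_by_se_and_sp(tp, fp, fn, tn):
    if tp + fn == 0 or tn + fp == 0:
        return
    se, sp, ac = se_sp_ac(ConfusionCounts(tp, fp, fn, tn))
    assert min(se, sp) - 1e-12 <= ac <= max(se, sp) + 1e-12
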