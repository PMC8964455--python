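"""Statistical layer: hand-computed chi-squared / point-biserial / logistic
values, exact band boundaries, and the screening + modelling report."""

import math

import numpy as np
import pandas as pd
import pytest

from penaltypose.errors import (
    DegenerateTableError,
    ModelFitError,
    UndefinedCorrelationError,
)
from penaltypose.strategy_stats import (
    build_design,
    chi_squared,
    cramers_v,
    effect_class,
    logistic_fit,
    point_biserial,
    reliability_band,
    retest_reliability,
    strategy_report,
    summarize_confidence,
)
from penaltypose.synthetic_scenes import (
    default_study_config,
    simulate_ospaf_dataset,
)


def pearson_oracle(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc)))


class TestChiSquared:
    def test_independent_table(self):
        res = chi_squared([[5, 5], [5, 5]])
        assert res.chi2 == 0.0
        assert res.cramers_v == 0.0
        assert res.effect_class == "weak"

    def test_perfect_diagonal(self):
        res = chi_squared([[10, 0], [0, 10]])
        assert res.chi2 == pytest.approx(20.0)
        assert res.df == 1
        assert res.cramers_v == pytest.approx(1.0)
        assert res.effect_class == "strong"

    def test_hand_computed_2x2(self):
        res = chi_squared([[8, 2], [3, 7]])
        assert res.chi2 == pytest.approx(5.0505, abs=1e-4)

    def test_permutation_invariance(self, rng):
        t = rng.integers(1, 30, size=(3, 4))
        base = chi_squared(t).chi2
        perm = t[rng.permutation(3)][:, rng.permutation(4)]
        assert chi_squared(perm).chi2 == pytest.approx(base)

    def test_diagonal_2x2_always_v1(self, rng):
        for _ in range(10):
            a, b = rng.integers(1, 50, size=2)
            res = chi_squared([[a, 0], [0, b]])
            assert res.cramers_v == pytest.approx(1.0)

    def test_empty_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            chi_squared([[5, 0], [7, 0]])


class TestCramersV:
    def test_reported_tactical_action_row(self):
        v, cls = cramers_v(26.542, 39, 2, 2)
        assert round(v, 3) == 0.825
        assert cls == "strong"

    def test_zero_statistic(self):
        assert cramers_v(0.0, 34, 2, 2) == (0.0, "weak")

    def test_perfect_association(self):
        v, cls = cramers_v(20.0, 20, 2, 2)
        assert v == pytest.approx(1.0)
        assert cls == "strong"


class TestPointBiserial:
    def test_equal_group_means_zero(self):
        r, _ = point_biserial([0, 0, 1, 1], [3.0, 5.0, 4.0, 4.0])
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_hand_example(self):
        r, _ = point_biserial([0, 0, 1, 1], [1.0, 2.0, 3.0, 4.0])
        assert r == pytest.approx(2 / math.sqrt(5), abs=1e-12)

    def test_matches_pearson_oracle(self, rng):
        y = rng.integers(0, 2, size=40)
        while len(np.unique(y)) < 2:
            y = rng.integers(0, 2, size=40)
        x = rng.normal(size=40)
        r, _ = point_biserial(y, x)
        assert r == pytest.approx(pearson_oracle(y, x), abs=1e-12)

    def test_constant_continuous_errors(self):
        with pytest.raises(UndefinedCorrelationError):
            point_biserial([0, 1, 0, 1], [2.0, 2.0, 2.0, 2.0])


class TestReliability:
    def test_identical_runs_perfect(self):
        res = retest_reliability([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.r == pytest.approx(1.0)
        assert res.band == "perfect"

    def test_hand_pearson_band(self):
        res = retest_reliability([1, 2, 3, 4], [1.1, 1.9, 3.2, 3.8])
        assert res.r == pytest.approx(0.9909, abs=1e-4)
        assert res.band == "excellent"

    def test_reported_nonkick_foot_value_banded(self):
        assert reliability_band(0.924) == "excellent"

    @pytest.mark.parametrize(
        "r,band",
        [
            (1.0, "perfect"),
            (0.95, "excellent"),
            (0.9, "excellent"),
            (0.8999, "good"),
            (0.8, "good"),
            (0.7, "acceptable"),
            (0.6999, "questionable"),
            (0.6, "questionable"),
            (0.5, "poor"),
            (0.4999, "unacceptable"),
            (0.0, "none"),
            (-0.3, "unacceptable"),
        ],
    )
    def test_band_boundaries_exact(self, r, band):
        assert reliability_band(r) == band

    def test_constant_run_errors(self):
        with pytest.raises(UndefinedCorrelationError):
            retest_reliability([2, 2, 2], [1, 2, 3])


class TestEffectClassBoundaries:
    @pytest.mark.parametrize(
        "v,cls",
        [(0.0, "weak"), (0.2, "weak"), (0.2000001, "moderate"),
         (0.6, "moderate"), (0.6000001, "strong"), (1.0, "strong")],
    )
    def test_step_function(self, v, cls):
        assert effect_class(v) == cls


class TestSummarizeConfidence:
    def test_per_variable_scores(self):
        assert summarize_confidence([0.51, 0.87, 0.85, 0.87, 0.84, 0.83]) == (0.80, 0.14)

    def test_constant_scores(self):
        mean, sd = summarize_confidence([0.7, 0.7, 0.7])
        assert (mean, sd) == (0.70, 0.0)

    def test_two_point_hand_value(self):
        assert summarize_confidence([0.0, 1.0]) == (0.50, 0.71)

    def test_too_short(self):
        with pytest.raises(UndefinedCorrelationError):
            summarize_confidence([0.8])


class TestLogisticFit:
    def test_null_model_balanced(self):
        y = [0] * 10 + [1] * 10
        m = logistic_fit(pd.DataFrame(index=range(20)), y)
        assert m.model_chi2 == pytest.approx(0.0, abs=1e-9)
        assert m.accuracy == pytest.approx(0.5)

    def test_saturated_2x2_closed_form(self):
        # groups: x=1 -> 8 positive / 2 negative; x=0 -> 3 positive / 7 negative
        x = [1] * 10 + [0] * 10
        y = [1] * 8 + [0] * 2 + [1] * 3 + [0] * 7
        m = logistic_fit(pd.DataFrame({"x": x}), y)
        assert m.coefficients["const"] == pytest.approx(math.log(3 / 7), abs=1e-6)
        assert m.coefficients["x"] == pytest.approx(math.log(28 / 3), abs=1e-6)
        # closed-form likelihood-ratio statistic of the saturated 2x2 model
        ll_full = 8 * math.log(0.8) + 2 * math.log(0.2) + 7 * math.log(0.7) + 3 * math.log(0.3)
        ll_null = 11 * math.log(0.55) + 9 * math.log(0.45)
        assert m.model_chi2 == pytest.approx(2 * (ll_full - ll_null), abs=1e-6)
        assert m.model_chi2 == pytest.approx(5.30, abs=5e-3)
        assert m.accuracy == pytest.approx(0.75)

    def test_perfect_separation_warns_and_classifies(self):
        x = np.concatenate([np.linspace(-3, -1, 8), np.linspace(1, 3, 8)])
        y = [0] * 8 + [1] * 8
        with pytest.warns(UserWarning, match="separation"):
            m = logistic_fit(pd.DataFrame({"x": x}), y)
        assert m.separation
        assert m.accuracy == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ModelFitError):
            logistic_fit(pd.DataFrame({"x": [1.0, 2.0]}), [1, 1])

    def test_nested_model_loglik_monotone(self, rng):
        n = 60
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = (x1 + rng.normal(scale=1.5, size=n) > 0).astype(int)
        small = logistic_fit(pd.DataFrame({"x1": x1}), y)
        big = logistic_fit(pd.DataFrame({"x1": x1, "x2": x2}), y)
        assert big.log_likelihood >= small.log_likelihood - 1e-8
        assert big.model_chi2 >= small.model_chi2 - 1e-8


class TestStrategyReport:
    def test_planted_association_retained(self):
        cfg = default_study_config(outcome="gk_strategy", n_penalties=200, seed=11)
        table, _ = simulate_ospaf_dataset(cfg)
        report = strategy_report(table, outcome="gk_strategy")
        assert "gk_tactical_action" in report.retained_categorical
        assert "alpha_gk" in report.retained_numeric
        # independent variables stay out
        assert "kick_direction" not in report.retained_categorical
        assert report.model_ospaf is not None
        assert report.model_with_pose.accuracy >= report.model_ospaf.accuracy

    def test_pose_variable_encoding_label_gives_perfect_second_model(self):
        cfg = default_study_config(outcome="gk_strategy", n_penalties=120, seed=5)
        table, _ = simulate_ospaf_dataset(cfg)
        # replace alpha_gk by an exact encoding of the label
        table = table.copy()
        table["alpha_gk"] = np.where(table["gk_strategy"] == "kicker_dependent", 1.0, 0.0)
        with pytest.warns(UserWarning, match="separation"):
            report = strategy_report(table, outcome="gk_strategy")
        assert report.model_with_pose.accuracy == 1.0
        assert report.model_with_pose.accuracy >= report.model_ospaf.accuracy

    def test_unclear_rows_excluded(self):
        cfg = default_study_config(outcome="gk_strategy", n_penalties=80, seed=2)
        table, _ = simulate_ospaf_dataset(cfg)
        table.loc[:4, "gk_strategy"] = "unclear"
        report = strategy_report(table, outcome="gk_strategy")
        assert report.n_excluded_unclear == 5
        assert report.n_used == 75

    def test_dummy_coding_reference_is_first_alphabetical(self):
        df = pd.DataFrame({"v": ["b", "a", "c", "a"]})
        design = build_design(df, categorical=["v"])
        assert list(design.columns) == ["v_b", "v_c"]
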