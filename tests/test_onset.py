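"""Survival estimates, log-rank, mean contrasts, logistic predictor."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from famseg.core_model import Affection, Individual
from famseg.onset_models import (
    compare_onset_means,
    fit_carrier_predictor,
    kaplan_meier,
    logrank_test,
    onset_observations,
)


def affected(i, aao, fam="F"):
    return Individual(
        individual_id=f"a{i}", family_id=fam,
        affection=Affection.AFFECTED, age_onset=aao,
    )


def censored(i, age, fam="F"):
    return Individual(
        individual_id=f"c{i}", family_id=fam,
        affection=Affection.UNAFFECTED, age_last_exam=age,
    )


class TestKaplanMeier:
    def test_reduces_to_empirical_survival_without_censoring(self):
        inds = [affected(i, t) for i, t in enumerate((60, 70, 80))]
        (curve,) = kaplan_meier(inds, lambda m: "all").values()
        assert curve.survival_at(65) == pytest.approx(2 / 3)
        assert curve.survival_at(75) == pytest.approx(1 / 3)
        assert curve.survival_at(59) == 1.0
        assert curve.survival_at(80) == pytest.approx(0.0)

    def test_censoring_before_event_reduces_risk_set(self):
        inds = [affected(0, 70), censored(1, 65)]
        (curve,) = kaplan_meier(inds, lambda m: "all").values()
        assert curve.times.tolist() == [70.0]
        assert curve.at_risk.tolist() == [1]
        assert curve.survival_at(70) == pytest.approx(0.0)

    def test_estimate_tracks_generating_survival_under_censoring(self):
        """500 individuals with normal onset and independent uniform
        censoring: the product-limit estimate at the true median is
        within 3 percentage points of 0.5."""
        rng = np.random.default_rng(42)
        inds = []
        for i in range(500):
            onset = rng.normal(72, 6)
            exam = rng.uniform(55, 95)
            if onset <= exam:
                inds.append(affected(i, float(onset)))
            else:
                inds.append(censored(i, float(exam)))
        (curve,) = kaplan_meier(inds, lambda m: "all").values()
        assert curve.survival_at(72.0) == pytest.approx(0.5, abs=0.03)

    def test_empty_group_omitted_with_warning(self):
        inds = [affected(0, 70)]
        grouping = lambda m: "a" if m.individual_id == "a0" else "b"
        with pytest.warns(UserWarning, match="omitted"):
            curves = kaplan_meier(
                inds + [Individual("x", "F", affection=Affection.UNKNOWN)],
                lambda m: "b" if m.affection is Affection.UNKNOWN else "a",
            )
        assert list(curves) == ["a"]


class TestLogrank:
    def test_identical_groups_give_null_result(self):
        g = ([60.0, 65.0, 70.0, 75.0, 80.0], [1, 1, 1, 1, 1])
        stat, p = logrank_test({"a": g, "b": g})
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    @staticmethod
    def _logrank_stat_by_hand(durs, in_a):
        """Independent two-group log-rank chi-square: sum over distinct
        event times of (observed - expected) in group a, variance from
        the hypergeometric at each risk set (all observations are events)."""
        o_minus_e = 0.0
        var = 0.0
        for t in np.unique(durs):
            at_risk = durs >= t
            n = at_risk.sum()
            n_a = (at_risk & in_a).sum()
            d = (durs == t).sum()
            d_a = ((durs == t) & in_a).sum()
            o_minus_e += d_a - d * n_a / n
            if n > 1:
                var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        return o_minus_e**2 / var

    def test_small_sample_p_matches_permutation_distribution(self):
        """Log-rank chi-square p on 5-per-arm data agrees with the label
        permutation distribution of the statistic within Monte-Carlo error."""
        durs = np.array([61, 64, 68, 72, 77, 66, 70, 74, 79, 83], dtype=float)
        in_a = np.array([True] * 5 + [False] * 5)
        obs_stat, obs_p = logrank_test(
            {
                "a": (durs[:5].tolist(), [1] * 5),
                "b": (durs[5:].tolist(), [1] * 5),
            }
        )
        assert obs_stat == pytest.approx(
            self._logrank_stat_by_hand(durs, in_a), rel=1e-9
        )
        rng = np.random.default_rng(7)
        perm_stats = np.empty(10000)
        lab = in_a.copy()
        for i in range(10000):
            rng.shuffle(lab)
            perm_stats[i] = self._logrank_stat_by_hand(durs, lab)
        p_perm = float(np.mean(perm_stats >= obs_stat - 1e-12))
        assert obs_p == pytest.approx(p_perm, abs=0.05)

    def test_detects_onset_shift_at_moderate_sample_size(self):
        rng = np.random.default_rng(5)
        early = rng.normal(69, 6, size=300)
        late = rng.normal(73, 6, size=300)
        stat, p = logrank_test(
            {
                "2_alleles": (early.tolist(), [1] * 300),
                "0_alleles": (late.tolist(), [1] * 300),
            }
        )
        assert p < 0.05

    def test_invariant_under_monotone_time_transformation(self):
        rng = np.random.default_rng(9)
        a = rng.normal(70, 5, 40)
        b = rng.normal(74, 5, 40)
        base = logrank_test(
            {"a": (a.tolist(), [1] * 40), "b": (b.tolist(), [1] * 40)}
        )
        warped = logrank_test(
            {
                "a": (np.exp(a / 20).tolist(), [1] * 40),
                "b": (np.exp(b / 20).tolist(), [1] * 40),
            }
        )
        assert base[0] == pytest.approx(warped[0], rel=1e-9)


class TestMeanContrast:
    def test_identical_degenerate_groups(self):
        out = compare_onset_means([70, 70], [70, 70])
        assert out["difference"] == 0.0
        assert out["p_welch"] == 1.0

    def test_simulated_carrier_shift_recovers_sign(self):
        """A -3 y carrier onset shift at n=60 vs 379: the sign is recovered
        essentially always and the contrast is detected in the typical
        replicate (median p over 20 draws below 0.05)."""
        rng = np.random.default_rng(12)
        signs, p_welch, p_wilcoxon = [], [], []
        for _ in range(20):
            carriers = rng.normal(67.5, 8, 60)
            noncarriers = rng.normal(70.5, 8, 379)
            out = compare_onset_means(carriers, noncarriers)
            signs.append(out["difference"] < 0)
            p_welch.append(out["p_welch"])
            p_wilcoxon.append(out["p_wilcoxon"])
        assert np.mean(signs) >= 0.9
        assert np.median(p_welch) < 0.05
        assert np.median(p_wilcoxon) < 0.05

    def test_tiny_group_reports_means_only(self):
        out = compare_onset_means([70.0], [65.0, 68.0])
        assert out["mean_a"] == 70.0
        assert out["p_welch"] is None


class TestPredictorModel:
    def test_binary_predictor_slope_equals_log_cross_product_or(self):
        """One binary covariate: the logistic slope must equal the log
        cross-product odds ratio of the implied 2x2 table."""
        a, b, c, d = 28, 411, 376, 12105
        df = pd.DataFrame(
            {
                "carrier": [1] * a + [0] * b + [1] * c + [0] * d,
                "familial": [1] * (a + b) + [0] * (c + d),
            }
        )
        model = fit_carrier_predictor(df, "carrier", ["familial"])
        expected = math.log((a * d) / (b * c))
        assert model.coefficients["familial"] == pytest.approx(
            expected, abs=1e-3
        )

    def test_constant_predictor_gives_prevalence_intercept(self):
        df = pd.DataFrame(
            {"carrier": [1] * 10 + [0] * 30, "x": [1.0] * 40}
        )
        model = fit_carrier_predictor(df, "carrier", [])
        assert model.intercept == pytest.approx(math.log(10 / 30), abs=1e-6)

    def test_uninformative_scores_give_chance_auc(self):
        df = pd.DataFrame({"carrier": [1, 0, 1, 0], "x": [2.0] * 4})
        model = fit_carrier_predictor(df, "carrier", ["x"])
        assert model.auc == pytest.approx(0.5)

    def test_auc_equals_mann_whitney_normalization(self):
        rng = np.random.default_rng(23)
        y = rng.integers(0, 2, 200)
        score = rng.normal(0, 1, 200) + 0.8 * y
        df = pd.DataFrame({"carrier": y, "x": score})
        model = fit_carrier_predictor(df, "carrier", ["x"])
        u = stats.mannwhitneyu(score[y == 1], score[y == 0]).statistic
        assert model.auc == pytest.approx(u / ((y == 1).sum() * (y == 0).sum()))

    def test_forward_stepwise_selects_informative_covariate(self):
        rng = np.random.default_rng(31)
        n = 400
        informative = rng.normal(0, 1, n)
        noise = rng.normal(0, 1, n)
        logit = -1 + 1.2 * informative
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        df = pd.DataFrame(
            {"carrier": y.astype(int), "signal": informative, "noise": noise}
        )
        model = fit_carrier_predictor(
            df, "carrier", ["noise", "signal"], stepwise=True
        )
        assert "signal" in model.selected
        assert "noise" not in model.selected

    def test_per_unit_odds_ratios_use_field_conventions(self):
        rng = np.random.default_rng(40)
        n = 300
        naff = rng.integers(4, 12, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-3 + 0.25 * naff)))).astype(int)
        df = pd.DataFrame({"carrier": y, "n_affected_reported": naff})
        model = fit_carrier_predictor(df, "carrier", ["n_affected_reported"])
        beta = model.coefficients["n_affected_reported"]
        assert model.or_per_unit["n_affected_reported"] == pytest.approx(
            math.exp(2 * beta)
        )


def test_onset_observations_skips_mci_and_unknown():
    inds = [
        affected(0, 70),
        censored(1, 65),
        Individual("m", "F", affection=Affection.MCI, age_last_exam=60),
        Individual("u", "F", affection=Affection.UNKNOWN),
    ]
    durs, events = onset_observations(inds)
    assert durs.tolist() == [70.0, 65.0]
    assert events.tolist() == [1, 0]
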