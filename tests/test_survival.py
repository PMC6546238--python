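"""Concordance index, penalized Cox development, follow-up estimation and
the univariable PET-metric analysis."""

import numpy as np
import pandas as pd
import pytest
from sksurv.metrics import concordance_index_censored

from deltarad import (SurvivalGroundTruth, breslow_loglik, draw_survival,
                      fit_lasso_cox, harrell_cindex, km_median_followup,
                      pi_range_summary, prognostic_index,
                      univariable_pet_metrics)

import oracles


class TestHarrellCindex:
    def test_perfect_ordering_gives_one(self):
        t = np.array([1.0, 2, 3, 4, 5])
        assert harrell_cindex(-t, t, np.ones(5)).estimate == 1.0

    def test_constant_pi_gives_half(self):
        t = np.array([1.0, 2, 3, 4, 5])
        assert harrell_cindex(np.zeros(5), t, np.ones(5)).estimate == 0.5

    def test_hand_listed_six_patients_match_enumeration(self):
        t = np.array([2.0, 5.0, 3.0, 3.0, 8.0, 1.0])
        e = np.array([1, 0, 1, 0, 1, 1])
        pi = np.array([0.9, -0.5, 0.4, 0.4, -1.0, 2.0])
        res = harrell_cindex(pi, t, e)
        assert res.estimate == pytest.approx(
            oracles.cindex_bruteforce(pi, t, e), abs=1e-12)
        assert res.lower95 <= res.estimate <= res.upper95

    def test_matches_bruteforce_on_random_data(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 25))
            t = rng.exponential(2.0, n).round(1)  # ties in time
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                e[0] = 1
            pi = rng.normal(size=n).round(1)      # ties in PI
            assert harrell_cindex(pi, t, e).estimate == pytest.approx(
                oracles.cindex_bruteforce(pi, t, e), abs=1e-9)

    def test_agrees_with_sksurv_library(self, rng):
        """Independent library cross-check (tie-free PI, where the usable-
        pair conventions coincide)."""
        n = 80
        t = rng.exponential(2.0, n)
        e = rng.integers(0, 2, n).astype(bool)
        e[0] = True
        pi = rng.normal(size=n)
        ours = harrell_cindex(pi, t, e.astype(int)).estimate
        theirs = concordance_index_censored(e, t, pi)[0]
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_antisymmetry(self, rng):
        n = 40
        t = rng.exponential(2.0, n)
        e = rng.integers(0, 2, n)
        e[0] = 1
        pi = rng.normal(size=n)
        c1 = harrell_cindex(pi, t, e).estimate
        c2 = harrell_cindex(-pi, t, e).estimate
        assert c1 == pytest.approx(1.0 - c2, abs=1e-12)

    def test_no_usable_pairs_raises(self):
        with pytest.raises(ValueError):
            harrell_cindex([1.0, 2.0], [1.0, 2.0], [0, 0])


class TestBreslowLoglik:
    def test_matches_lifelines_at_fixed_coefficient(self, rng):
        from lifelines import CoxPHFitter

        n = 60
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x))
        e = rng.integers(0, 2, n)
        e[:5] = 1
        df = pd.DataFrame({"x": x, "t": t, "e": e})
        cph = CoxPHFitter()
        cph.fit(df, "t", "e")
        beta = float(cph.params_["x"])
        ours = breslow_loglik(beta * x, t, e)
        assert ours == pytest.approx(float(cph.log_likelihood_), rel=1e-6)


def _survival_data(rng, n, beta, p_noise=20, censor=0.3):
    X = rng.standard_normal((n, p_noise + 1))
    truth = SurvivalGroundTruth(baseline_hazard_scale=0.5,
                                censoring_rate_target=censor)
    t, e = draw_survival(beta * X[:, 0], truth, rng)
    cols = ["signal"] + [f"noise{i}" for i in range(p_noise)]
    return pd.DataFrame(X, columns=cols), t, e


class TestLassoCox:
    def test_signal_feature_recovered(self, rng):
        feats, t, e = _survival_data(rng, 200, beta=1.0)
        res = fit_lasso_cox(feats, t, e, n_repeats=3, seed=0)
        assert not res.empty_model
        assert res.coefficients.get("signal", 0.0) > 0

    def test_pure_noise_gives_empty_model(self, rng):
        feats, t, e = _survival_data(rng, 100, beta=0.0)
        res = fit_lasso_cox(feats, t, e, n_repeats=3, seed=0)
        assert res.empty_model
        assert (prognostic_index(res, feats) == 0).all()

    def test_training_standardization_reused_for_scoring(self, rng):
        feats, t, e = _survival_data(rng, 150, beta=1.0)
        res = fit_lasso_cox(feats, t, e, n_repeats=2, seed=1)
        rescored = res.prognostic_index(feats)
        pd.testing.assert_series_equal(rescored, res.training_pi,
                                       check_exact=False, atol=1e-12)

    def test_pi_ordering_invariant_to_feature_shift_on_refit(self, rng):
        feats, t, e = _survival_data(rng, 150, beta=1.0, p_noise=5)
        r1 = fit_lasso_cox(feats, t, e, n_repeats=2, seed=2)
        shifted = feats + 100.0
        r2 = fit_lasso_cox(shifted, t, e, n_repeats=2, seed=2)
        pi1 = r1.prognostic_index(feats)
        pi2 = r2.prognostic_index(shifted)
        assert np.all(np.argsort(pi1.values) == np.argsort(pi2.values))

    def test_few_events_reduces_folds_with_warning(self, rng, caplog):
        feats, t, e = _survival_data(rng, 40, beta=0.5, p_noise=3)
        e[:] = 0
        e[:5] = 1
        with caplog.at_level("WARNING"):
            res = fit_lasso_cox(feats, t, e, n_folds=10, n_repeats=1, seed=0)
        assert "reducing folds" in caplog.text

    def test_missing_and_constant_features_prefiltered(self, rng):
        feats, t, e = _survival_data(rng, 100, beta=1.0, p_noise=3)
        feats["allnan"] = np.nan
        feats["const"] = 2.0
        res = fit_lasso_cox(feats, t, e, n_repeats=1, seed=0)
        assert "allnan" not in res.feature_names
        assert "const" not in res.feature_names

    def test_prognostic_index_hand_example(self, rng):
        feats, t, e = _survival_data(rng, 100, beta=1.0, p_noise=2)
        res = fit_lasso_cox(feats, t, e, n_repeats=2, seed=0)
        if not res.empty_model:
            x = feats.iloc[[0]]
            xs = (x[res.feature_names] - res.feature_means) / res.feature_sds
            manual = sum(res.coefficients[k] * xs.iloc[0][k]
                         for k in res.coefficients.index)
            assert res.prognostic_index(x).iloc[0] == pytest.approx(manual)

    def test_pi_range_summary_per_cohort(self):
        pi = pd.Series([0.0, 1.0, 2.0, 3.0], index=list("abcd"))
        cohorts = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        out = pi_range_summary(pi, cohorts)
        assert out.loc["x", "max"] == 1.0 and out.loc["y", "min"] == 2.0


class TestKmMedianFollowup:
    def test_all_censored_at_five(self):
        out = km_median_followup(np.full(10, 5.0), np.zeros(10, int))
        assert out["median_followup"] == 5.0

    def test_all_events_not_reached(self):
        out = km_median_followup(np.arange(1.0, 9.0), np.ones(8, int))
        assert out["not_reached"]

    def test_hand_computed_product_limit_table(self):
        """8 patients, reversed events (deaths censored): follow-up curve
        steps at censoring times 2, 4, 6, 8; hand product-limit gives
        S(4) = 7/8 * 5/6 * ... median where curve <= 0.5."""
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        e = np.array([1, 0, 1, 0, 1, 0, 1, 0])  # deaths at odd times
        # reversed: events at 2,4,6,8; risk sets 7,5,3,1
        # S(2)=6/7, S(4)=6/7*4/5=0.686, S(6)=0.686*2/3=0.457 <= 0.5
        out = km_median_followup(t, e)
        assert out["median_followup"] == pytest.approx(6.0)


class TestUnivariablePetMetrics:
    def test_null_covariate_ci_contains_one(self, rng):
        n = 300
        pre = pd.DataFrame({"volume": rng.uniform(1e3, 1e5, n)})
        during = pd.DataFrame({"volume": pre["volume"]
                               * rng.uniform(0.5, 1.0, n)})
        truth = SurvivalGroundTruth(censoring_rate_target=0.3)
        t, e = draw_survival(np.zeros(n), truth, rng)
        out = univariable_pet_metrics(pre, during, t, e, metrics=("volume",))
        row = out.loc["volume"]
        assert row["hr_ci_low"] <= 1.0 <= row["hr_ci_high"]
        assert row["pct_change_mean"] < 0  # shrinkage reports negative

    def test_recovers_log_hazard_coefficient(self, rng):
        n = 1000
        change = rng.normal(0.0, 1.0, n)
        truth = SurvivalGroundTruth(baseline_hazard_scale=0.5,
                                    censoring_rate_target=0.2)
        t, e = draw_survival(0.7 * change, truth, rng)
        pre = pd.DataFrame({"suvmax": np.ones(n)})
        during = pd.DataFrame({"suvmax": 1.0 + change})
        out = univariable_pet_metrics(pre, during, t, e, metrics=("suvmax",))
        assert out.loc["suvmax", "log_hr"] == pytest.approx(0.7, abs=0.15)

    def test_uniform_sphere_peak_equals_mean_equals_max(self, sphere_mask):
        from deltarad import ImageVolume, compute_pet_metrics

        img = ImageVolume(np.full(sphere_mask.shape, 5.0),
                          sphere_mask.spacing, modality="PET-SUV")
        m = compute_pet_metrics(img, sphere_mask)
        assert m["suvmax"] == m["suvmean"] == pytest.approx(m["suvpeak"])
        assert m["mtv50"] == pytest.approx(sphere_mask.volume_mm3)
        assert m["tlg50"] == pytest.approx(sphere_mask.volume_mm3 * 5.0)
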