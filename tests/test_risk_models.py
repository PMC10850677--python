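import numpy as np
import pandas as pd
import pytest

import vcgtwist as v
from vcgtwist.errors import DataError, FitError, SpecError


def _mini_cohort(**cols):
    """Tiny hand-written cohort with all schema columns present."""
    n = len(next(iter(cols.values()))) if cols else 3
    base = {
        "age": [60.0] * n,
        "female": [0.0] * n,
        "ischaemic": [1.0] * n,
        "crt_d": [0.0] * n,
        "heart_rate": [70.0] * n,
        "lvef": [26.0] * n,
        "qrs_duration": [130.0] * n,
        "qtc": [440.0] * n,
        "tpte": [95.0] * n,
        "qrst_angle": [140.0] * n,
        "npl_qrs_8": [4.0] * n,
        "npl_t_8": [3.0] * n,
        "npl_qrs_3": [4.0] * n,
        "npl_t_3": [3.0] * n,
        "death_time": [1000.0] * n,
        "death_event": [0] * n,
        "shock_time": [1000.0] * n,
        "shock_event": [0] * n,
    }
    base.update(cols)
    return pd.DataFrame(base)


class TestFollowUpRules:
    def test_death_after_horizon_censored_at_horizon(self):
        df = _mini_cohort(death_time=[2000.0, 500.0], death_event=[1, 1])
        out = v.apply_follow_up_rules(df)
        assert out.loc[0, "death_time"] == 1826 and out.loc[0, "death_event"] == 0
        assert out.loc[1, "death_time"] == 500 and out.loc[1, "death_event"] == 1

    def test_death_without_shock_censors_shock_at_death(self):
        # patient dies at day 278 without any shock
        df = _mini_cohort(
            death_time=[278.0], death_event=[1], shock_time=[1800.0], shock_event=[0]
        )
        out = v.apply_follow_up_rules(df)
        assert out.loc[0, "shock_time"] == 278 and out.loc[0, "shock_event"] == 0

    def test_shock_then_death_counts_in_both_endpoints(self):
        df = _mini_cohort(
            death_time=[300.0], death_event=[1], shock_time=[100.0], shock_event=[1]
        )
        out = v.apply_follow_up_rules(df)
        assert out.loc[0, "shock_time"] == 100 and out.loc[0, "shock_event"] == 1
        assert out.loc[0, "death_time"] == 300 and out.loc[0, "death_event"] == 1

    def test_unknown_shock_rows_stay_nan_and_are_excluded(self):
        df = _mini_cohort(shock_time=[np.nan, 400.0], shock_event=[np.nan, 1])
        out = v.apply_follow_up_rules(df)
        assert np.isnan(out.loc[0, "shock_time"])
        from vcgtwist.risk_models import endpoint_frame

        sub, *_ = endpoint_frame(out, "shock")
        assert len(sub) == 1

    def test_negative_times_rejected(self):
        df = _mini_cohort(death_time=[-1.0])
        with pytest.raises(DataError):
            v.apply_follow_up_rules(df)


class TestTransforms:
    def test_log2_values(self):
        df = _mini_cohort(npl_qrs_8=[4.0, 1.0, 8.0])
        out = v.transform_npl(df)
        np.testing.assert_allclose(out["log2_npl_qrs_8"], [2.0, 0.0, 3.0])

    def test_doubling_adds_one(self):
        df = _mini_cohort(npl_t_8=[2.5, 5.0])
        out = v.transform_npl(df)
        assert out["log2_npl_t_8"][1] - out["log2_npl_t_8"][0] == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(DataError):
            v.transform_npl(_mini_cohort(npl_qrs_8=[0.0, 4.0]))


class TestDichotomize:
    def test_strict_boundaries(self):
        df = _mini_cohort(age=[75.0, 75.1], lvef=[25.0, 20.0])
        out, thr = v.dichotomize(df)
        assert list(out["age_gt75"]) == [0, 1]
        assert list(out["lvef_lt25"]) == [0, 1]
        assert thr["age_gt75"] == 75.0

    def test_npl_median_split_is_data_driven(self):
        vals = [2.0, 3.0, 4.49, 4.50, 6.0, 9.0]
        df = _mini_cohort(npl_qrs_8=vals)
        out, thr = v.dichotomize(df)
        med = thr["npl_qrs_8_gt_median"]
        assert med == pytest.approx(np.median(vals))
        assert list(out["npl_qrs_8_gt_median"]) == [0, 0, 0, 1, 1, 1]

    def test_missing_column_rejected(self):
        df = _mini_cohort().drop(columns=["qtc"])
        with pytest.raises(DataError):
            v.dichotomize(df)


class TestSimulateCohort:
    def test_seed_determinism(self):
        spec = v.CohortSimSpec(n=200, seed=5)
        pd.testing.assert_frame_equal(v.simulate_cohort(spec), v.simulate_cohort(spec))

    def test_event_fraction_matches_censoring_target(self):
        # with all HRs at 1 and pure exponential clocks, the censored
        # fraction is censor_rate / (censor_rate + event_rate)
        lam, target_censor = 8.9e-5, 0.30
        mu = lam * target_censor / (1 - target_censor)
        spec = v.CohortSimSpec(
            n=10_000, seed=2, censor_rate_per_day=mu, admin_horizon_days=None,
            shock_unknown_fraction=0.0,
        )
        df = v.simulate_cohort(spec)
        censored = 1.0 - df["death_event"].mean()
        assert censored == pytest.approx(target_censor, abs=0.02)

    def test_unknown_covariate_rejected(self):
        with pytest.raises(SpecError):
            v.CohortSimSpec(log_hrs={"nonexistent": 0.5})


class TestCoxFit:
    def test_true_hazard_ratio_recovered(self):
        reps, hrs = 20, []
        for seed in range(reps):
            spec = v.CohortSimSpec(
                n=2000, seed=seed,
                custom_covariates={"x": ("normal", 0.0, 1.0)},
                log_hrs={"x": float(np.log(1.5))},
            )
            df = v.apply_follow_up_rules(v.simulate_cohort(spec))
            fit = v.fit_cox(df, "death", ["x"], mode="multivariable")
            hrs.append(fit.table.loc["x", "hr"])
        assert 1.4 < float(np.mean(hrs)) < 1.6

    def test_wald_is_square_of_z_and_ci_brackets_hr(self):
        spec = v.CohortSimSpec(n=1500, seed=3, log_hrs={"age": 0.03})
        df = v.apply_follow_up_rules(v.simulate_cohort(spec))
        fit = v.fit_cox(df, "death", ["age", "lvef"], mode="univariable")
        t = fit.table
        assert (t["hr_lo"] <= t["hr"]).all() and (t["hr"] <= t["hr_hi"]).all()
        assert (t["wald"] >= 0).all()
        np.testing.assert_allclose(t["hr"], np.exp(t["coef"]), rtol=1e-10)

    def test_constant_covariate_rejected(self):
        spec = v.CohortSimSpec(n=500, seed=1)
        df = v.apply_follow_up_rules(v.simulate_cohort(spec))
        df["flat"] = 1.0
        with pytest.raises(FitError):
            v.fit_cox(df, "death", ["flat"])

    def test_event_floor_enforced(self):
        df = _mini_cohort(death_event=[1, 0, 0], death_time=[10.0, 20.0, 30.0])
        with pytest.raises(FitError):
            v.fit_cox(df, "death", ["age"])


class TestBackwardsStepwise:
    def _cohort_with_signal_and_noise(self, seed):
        spec = v.CohortSimSpec(
            n=2000, seed=seed,
            custom_covariates={
                "signal": ("bernoulli", 0.5),
                "noise": ("normal", 0.0, 1.0),
            },
            log_hrs={"signal": float(np.log(2.0))},
        )
        return v.apply_follow_up_rules(v.simulate_cohort(spec))

    def test_signal_retained_noise_dropped(self):
        kept_signal = dropped_noise = 0
        reps = 20
        for seed in range(reps):
            df = self._cohort_with_signal_and_noise(seed)
            fit = v.backwards_stepwise(df, "death", ["signal", "noise"])
            kept_signal += "signal" in fit.covariates
            dropped_noise += "noise" not in fit.covariates
        assert kept_signal >= int(0.9 * reps)
        assert dropped_noise >= int(0.8 * reps)

    def test_single_significant_candidate_is_fixed_point(self):
        df = self._cohort_with_signal_and_noise(0)
        fit = v.backwards_stepwise(df, "death", ["signal"])
        assert fit.covariates == ("signal",) and fit.eliminated == ()

    def test_all_noise_can_empty_without_error(self):
        spec = v.CohortSimSpec(
            n=500, seed=11, custom_covariates={"n1": ("normal", 0, 1)}
        )
        df = v.apply_follow_up_rules(v.simulate_cohort(spec))
        fit = v.backwards_stepwise(df, "death", ["n1"])
        # either retained by chance (~alpha) or emptied cleanly
        assert fit.is_empty() or fit.covariates == ("n1",)


class TestKaplanMeier:
    def test_reduces_to_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(500, size=200)
        df = _mini_cohort(
            death_time=list(t), death_event=[1] * 200,
            crt_d=list(rng.binomial(1, 0.5, 200).astype(float)),
        )
        km = v.km_logrank(df, "death", "crt_d")
        for lev in ("0.0", "1.0"):
            sub = t[df["crt_d"].to_numpy() == float(lev)]
            # survival at each event time equals the empirical tail fraction
            times = km.survival.index.to_numpy()
            emp = [(sub > u).mean() for u in times]
            np.testing.assert_allclose(km.survival[lev].to_numpy(), emp, atol=1e-10)

    def test_separated_strata_detected(self):
        spec = v.CohortSimSpec(
            n=1000, seed=8,
            custom_covariates={"grp": ("bernoulli", 0.5)},
            log_hrs={"grp": float(np.log(2.0))},
        )
        df = v.apply_follow_up_rules(v.simulate_cohort(spec))
        km = v.km_logrank(df, "death", "grp")
        assert km.logrank_p < 0.05
        for col in km.survival.columns:
            s = km.survival[col].dropna().to_numpy()
            assert s[0] <= 1.0 and np.all(np.diff(s) <= 1e-12)
        assert (km.at_risk.diff(axis=1).fillna(0) <= 0).all().all()

    def test_no_events_rejected(self):
        df = _mini_cohort(crt_d=[0.0, 1.0, 0.0])
        with pytest.raises(DataError):
            v.km_logrank(df, "death", "crt_d")
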