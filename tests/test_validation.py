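import numpy as np
import pandas as pd
import pytest

from pacemeter import (
    PacemeterError,
    change_analysis,
    cox_hr,
    effect_size_r,
    group_contrast,
    poisson_irr,
    simulate_survival,
    simulate_trial,
    trial_interaction_model,
    within_person_change,
)


def _series(rng, n, loc=0.0, scale=1.0):
    return pd.Series(loc + scale * rng.standard_normal(n),
                     index=[f"s{i}" for i in range(n)])


class TestEffectSizeR:
    def test_identity_gives_r_one(self, rng):
        x = _series(rng, 50)
        es = effect_size_r(x, x.copy())
        assert es.estimate == pytest.approx(1.0)

    def test_equals_pearson_without_covariates(self, rng):
        y, x = _series(rng, 300), _series(rng, 300)
        y = y + 0.3 * x
        es = effect_size_r(y, x)
        assert es.estimate == pytest.approx(np.corrcoef(y, x)[0, 1], abs=1e-10)

    def test_independent_pair_within_null_band(self, rng):
        y, x = _series(rng, 1000), _series(rng, 1000)
        es = effect_size_r(y, x)
        assert abs(es.estimate) < 2 / np.sqrt(1000)

    def test_affine_rescaling_invariance(self, rng):
        y, x = _series(rng, 200), _series(rng, 200)
        a = effect_size_r(y, x)
        b = effect_size_r(y, 100.0 + 42.0 * x)
        assert b.estimate == pytest.approx(a.estimate, abs=1e-12)
        assert b.se == pytest.approx(a.se, abs=1e-12)

    def test_cluster_errors_widen_with_shared_noise(self, rng):
        n_fam, per = 100, 2
        fam = np.repeat(np.arange(n_fam), per)
        shared = rng.standard_normal(n_fam)[fam]
        idx = [f"s{i}" for i in range(n_fam * per)]
        x = pd.Series(rng.standard_normal(n_fam * per), index=idx)
        y = pd.Series(shared + 0.2 * rng.standard_normal(n_fam * per), index=idx)
        plain = effect_size_r(y, x)
        clustered = effect_size_r(y, x, cluster=pd.Series(fam, index=idx))
        assert clustered.se > 0
        assert clustered.estimate == pytest.approx(plain.estimate, abs=1e-12)

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(PacemeterError):
            effect_size_r(pd.Series([1.0, 1.0, 1.0]), pd.Series([1., 2., 3.]))


class TestChangeAnalysis:
    def test_no_change_is_degenerate(self, rng):
        y = _series(rng, 30)
        sc = _series(rng, 30)
        with pytest.raises(PacemeterError, match="variance"):
            change_analysis(y, y.copy(), sc, mode="difference")

    def test_planted_decline_detected_by_both_modes(self, rng):
        # baseline persistence b < 0.5: regression to the mean makes the
        # raw difference noisier than the baseline-adjusted follow-up, so
        # the residualized estimate dominates in expectation
        n = 600
        sc = _series(rng, n)
        base = _series(rng, n, loc=100, scale=15)
        fol = 0.4 * base - 3.0 * sc + _series(rng, n, scale=5)
        d = change_analysis(fol, base, sc, mode="difference")
        r = change_analysis(fol, base, sc, mode="residualized")
        assert d.estimate < 0 and r.estimate < 0
        assert abs(r.estimate) >= abs(d.estimate) - 0.05

    def test_independent_score_within_null_band(self, rng):
        n = 800
        sc = _series(rng, n)
        base = _series(rng, n)
        fol = 0.7 * base + _series(rng, n, scale=0.5)
        for mode in ("difference", "residualized"):
            es = change_analysis(fol, base, sc, mode=mode)
            assert abs(es.estimate) < 3 / np.sqrt(n)


class TestPoissonIRR:
    def test_null_ci_covers_one(self, rng):
        cnt = pd.Series(rng.poisson(2.0, 500).astype(float),
                        index=[f"s{i}" for i in range(500)])
        sc = _series(rng, 500)
        es = poisson_irr(cnt, sc)
        assert es.ci_low <= 1.0 <= es.ci_high

    def test_planted_log_rate_recovered(self, rng):
        n = 2000
        sc = _series(rng, n)
        z = (sc - sc.mean()) / sc.std(ddof=0)
        lam = np.exp(np.log(1.5) + 0.15 * z)
        cnt = pd.Series(rng.poisson(lam).astype(float), index=sc.index)
        es = poisson_irr(cnt, sc)
        assert es.ci_low <= np.exp(0.15) <= es.ci_high

    def test_non_integer_and_all_zero_rejected(self, rng):
        sc = _series(rng, 10)
        with pytest.raises(PacemeterError):
            poisson_irr(pd.Series(0.5, index=sc.index), sc)
        with pytest.raises(PacemeterError):
            poisson_irr(pd.Series(0.0, index=sc.index), sc)


class TestCoxHR:
    def test_null_ci_covers_one_and_strata_counts(self, rng):
        sc = _series(rng, 400, loc=1.0, scale=0.07)
        surv, _ = simulate_survival(sc, log_hr_per_sd=0.0, censor_rate=0.3, seed=3)
        res = cox_hr(surv["time"], surv["event"], surv["score"])
        assert res.effect.ci_low <= 1.0 <= res.effect.ci_high
        # independent threshold pass over raw scores
        z = (sc - sc.mean()) / sc.std(ddof=0)
        assert (res.strata == "slow").sum() == int((z <= -1).sum())
        assert (res.strata == "fast").sum() == int((z >= 1).sum())
        assert set(res.km_curves) == {"slow", "average", "fast"}

    def test_planted_hazard_recovered(self, rng):
        sc = _series(rng, 600, loc=1.0, scale=0.07)
        surv, _ = simulate_survival(sc, log_hr_per_sd=0.25, censor_rate=0.3, seed=7)
        res = cox_hr(surv["time"], surv["event"], surv["score"])
        assert res.effect.ci_low <= np.exp(0.25) <= res.effect.ci_high

    def test_no_events_rejected(self, rng):
        t = pd.Series(rng.uniform(1, 5, 20))
        with pytest.raises(PacemeterError):
            cox_hr(t, pd.Series(0, index=t.index), _series(rng, 20))


class TestWithinPersonChange:
    def _long(self, rng, n_subj, slope, level_sd=1.0, noise=0.05):
        t = np.tile([0.0, 3.0, 6.0, 9.0], n_subj)
        subj = np.repeat(np.arange(n_subj), 4)
        level = level_sd * rng.standard_normal(n_subj)[subj]
        return pd.DataFrame({
            "subject_id": subj, "time_years": t,
            "score": 1.0 + level + slope * t + noise * rng.standard_normal(len(t)),
        })

    def test_constant_scores_give_zero_slope(self, rng):
        df = self._long(rng, 40, slope=0.0, noise=0.0)
        es = within_person_change(df)
        assert es.estimate == pytest.approx(0.0, abs=1e-12)

    def test_planted_slope_recovered_per_five_years(self, rng):
        df = self._long(rng, 300, slope=0.002)
        es = within_person_change(df, unit_years=5.0)
        assert abs(es.estimate - 0.010) < 2 * es.se

    def test_between_person_shifts_do_not_bias(self, rng):
        df = self._long(rng, 100, slope=0.002, noise=0.0)
        a = within_person_change(df)
        df2 = df.copy()
        df2["score"] += df2["subject_id"] * 10.0  # huge level shifts
        b = within_person_change(df2)
        assert b.estimate == pytest.approx(a.estimate, abs=1e-9)

    def test_needs_repeated_measures(self, rng):
        df = pd.DataFrame({"subject_id": [1, 2], "time_years": [0, 0],
                           "score": [1.0, 2.0]})
        with pytest.raises(PacemeterError):
            within_person_change(df)


class TestGroupContrast:
    def test_exact_one_sd_shift_gives_d_one(self, rng):
        base = rng.standard_normal(200)
        base = (base - base.mean()) / base.std(ddof=1)
        idx = [f"s{i}" for i in range(400)]
        score = pd.Series(np.concatenate([base, base + 1.0]), index=idx)
        group = pd.Series(["a"] * 200 + ["b"] * 200, index=idx)
        res = group_contrast(score, group)
        assert res.pairwise_d["b"].estimate == pytest.approx(1.0, abs=1e-10)

    def test_identical_groups_cover_zero(self, rng):
        score = _series(rng, 300)
        group = pd.Series(rng.integers(0, 2, 300), index=score.index)
        res = group_contrast(score, group)
        es = res.pairwise_d["1"]
        assert es.ci_low <= 0.0 <= es.ci_high

    def test_monotone_gradient_detected(self, rng):
        n = 600
        group = pd.Series(rng.integers(0, 3, n), index=[f"s{i}" for i in range(n)])
        score = pd.Series(0.4 * group.to_numpy()
                          + rng.standard_normal(n), index=group.index)
        res = group_contrast(score, group, order=[0, 1, 2])
        assert res.trend.estimate > 0
        assert res.pairwise_d["2"].estimate > res.pairwise_d["1"].estimate > 0

    def test_small_group_rejected(self, rng):
        score = _series(rng, 10)
        group = pd.Series(["a"] * 9 + ["b"], index=score.index)
        with pytest.raises(PacemeterError):
            group_contrast(score, group)


class TestTrialInteraction:
    def test_null_interaction_ci_covers_zero(self):
        long, _ = simulate_trial(n=200, interaction=0.0, seed=42)
        res = trial_interaction_model(long)
        assert res.interaction.ci_low <= 0.0 <= res.interaction.ci_high

    def test_planted_interaction_recovered(self):
        long, truth = simulate_trial(n=220, interaction=-0.30, seed=10)
        res = trial_interaction_model(long)
        assert res.interaction.ci_low <= -0.30 <= res.interaction.ci_high

    def test_predicted_slopes_match_hand_linear_algebra(self):
        long, _ = simulate_trial(n=150, seed=5)
        res = trial_interaction_model(long)
        ctrl_gap = res.predicted_slopes["control_fast"] \
            - res.predicted_slopes["control_slow"]
        treat_gap = res.predicted_slopes["treatment_fast"] \
            - res.predicted_slopes["treatment_slow"]
        # fast-slow gap differs between arms by exactly twice the 3-way term
        assert treat_gap - ctrl_gap == pytest.approx(
            2.0 * res.interaction.estimate, abs=1e-9)
        assert ctrl_gap == pytest.approx(
            2.0 * res.control_slope_per_sd.estimate, abs=1e-9)

    def test_non_binary_condition_rejected(self):
        long, _ = simulate_trial(n=60, seed=1)
        long["condition"] = long["condition"] + 1
        with pytest.raises(PacemeterError):
            trial_interaction_model(long)
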