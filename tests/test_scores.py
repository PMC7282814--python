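import numpy as np
import pandas as pd
import pytest

from pacemeter import (
    BetaMatrix,
    ClockCalibration,
    PacemeterError,
    WeightModel,
    age_acceleration,
    probe_overlap,
    residualize,
    score,
)


def _beta(vals, probes=None, samples=None):
    probes = probes or [f"cg{i}" for i in range(len(vals))]
    samples = samples or [f"s{j}" for j in range(len(vals[0]))]
    return BetaMatrix(pd.DataFrame(vals, index=probes, columns=samples))


class TestScore:
    def test_hand_arithmetic(self):
        beta = _beta([[0.8], [0.5], [0.2]])
        model = WeightModel(1.0, pd.Series({"cg0": 0.5, "cg1": -0.2, "cg2": 0.1}))
        out = score(beta, model)
        assert out["score"].iloc[0] == pytest.approx(1.32)
        assert out["score_n_imputed"].iloc[0] == 0

    def test_intercept_only_and_zero_weight_models_are_constant(self, rng):
        beta = _beta(rng.random((5, 4)))
        const = score(beta, WeightModel(2.5, pd.Series(dtype=float)))
        np.testing.assert_allclose(const["score"], 2.5)
        zero = WeightModel(2.5, pd.Series(0.0, index=[f"cg{i}" for i in range(5)]))
        np.testing.assert_allclose(score(beta, zero)["score"], 2.5)

    def test_matches_naive_per_sample_loop(self, rng):
        n_probes, n_samples = 50, 20
        beta = _beta(rng.random((n_probes, n_samples)))
        w = pd.Series(rng.normal(0, 0.3, 30),
                      index=[f"cg{i}" for i in range(0, 60, 2)][:30])
        w = w[w.index.isin(beta.values.index)]
        model = WeightModel(-0.7, w)
        out = score(beta, model)["score"]
        for s in beta.sample_ids:
            naive = model.intercept + sum(
                model.weights[p] * beta.values.loc[p, s] for p in model.probe_ids)
            assert out[s] == pytest.approx(naive, abs=1e-12)

    def test_linearity_of_sample_mixture(self, rng):
        beta = _beta(rng.random((10, 2)))
        mix = BetaMatrix(pd.DataFrame(
            {"m": beta.values.mean(axis=1)}, index=beta.probe_ids))
        model = WeightModel(0.3, pd.Series(
            rng.normal(size=10), index=beta.probe_ids))
        s = score(beta, model)["score"]
        sm = score(mix, model)["score"]
        assert sm["m"] == pytest.approx((s.iloc[0] + s.iloc[1]) / 2, abs=1e-12)

    def test_order_invariance(self, rng):
        beta = _beta(rng.random((8, 6)))
        model = WeightModel(0.1, pd.Series(rng.normal(size=8), index=beta.probe_ids))
        base = score(beta, model)["score"]
        shuffled = BetaMatrix(beta.values.sample(frac=1, random_state=0)
                              .sample(frac=1, axis=1, random_state=1))
        again = score(shuffled, model)["score"]
        pd.testing.assert_series_equal(base.sort_index(), again.sort_index())

    def test_mean_impute_equals_filling_cohort_means(self, rng):
        vals = rng.random((6, 10))
        beta_full = _beta(vals.copy())
        vals_missing = vals.copy()
        vals_missing[2, 3] = np.nan
        vals_missing[5, 0] = np.nan
        beta_miss = _beta(vals_missing)
        model = WeightModel(0.0, pd.Series(rng.normal(size=6),
                                           index=beta_full.probe_ids))
        filled = vals.copy()
        filled[2, 3] = np.nanmean(vals_missing[2])
        filled[5, 0] = np.nanmean(vals_missing[5])
        expected = score(_beta(filled), model)["score"]
        got = score(beta_miss, model, missing_policy="mean_impute")
        pd.testing.assert_series_equal(got["score"], expected, check_names=False)
        assert got["score_n_imputed"].loc["s3"] == 1

    def test_fail_policy_lists_missing_probes(self, rng):
        vals = rng.random((4, 3))
        vals[1, 1] = np.nan
        beta = _beta(vals)
        model = WeightModel(0.0, pd.Series(1.0, index=beta.probe_ids))
        with pytest.raises(PacemeterError, match="cg1"):
            score(beta, model, missing_policy="fail")

    def test_reference_impute_covers_absent_probe(self, rng):
        beta = _beta(rng.random((3, 2)), probes=["cg0", "cg1", "cg2"])
        model = WeightModel(0.0, pd.Series(
            {"cg0": 1.0, "cg1": 1.0, "cg2": 1.0, "cg9": 2.0}))
        ref = pd.Series({"cg9": 0.25})
        out = score(beta, model, missing_policy="reference_impute", reference=ref)
        expected = beta.values.sum(axis=0) + 2.0 * 0.25
        np.testing.assert_allclose(out["score"], expected)
        with pytest.raises(PacemeterError, match="cg9"):
            score(beta, model, missing_policy="mean_impute")

    def test_all_probes_missing_rejected(self, rng):
        beta = _beta(rng.random((3, 2)))
        model = WeightModel(0.0, pd.Series({"cgX": 1.0}))
        with pytest.raises(PacemeterError, match="all model probes"):
            score(beta, model)


class TestCalibration:
    def test_piecewise_log_transform_values(self):
        cal = ClockCalibration(kind="anti_log_linear", adult_age=20)
        assert cal.apply(np.array([0.0]))[0] == pytest.approx(20.0)
        assert cal.apply(np.array([1.0]))[0] == pytest.approx(41.0)
        assert cal.apply(np.array([-1.0]))[0] == pytest.approx(21 * np.exp(-1) - 1)

    def test_invertibility(self, rng):
        cal = ClockCalibration(kind="anti_log_linear", adult_age=20)
        raw = rng.uniform(-3, 3, 100)
        np.testing.assert_allclose(cal.invert(cal.apply(raw)), raw, atol=1e-12)

    def test_unknown_kind_rejected(self):
        with pytest.raises(PacemeterError):
            ClockCalibration(kind="quadratic")


class TestResidualize:
    def test_orthogonal_covariate_leaves_score_unchanged(self, rng):
        n = 100
        idx = [f"s{i}" for i in range(n)]
        cov = rng.standard_normal(n)
        cov_c = cov - cov.mean()  # the design includes an intercept
        raw = rng.standard_normal(n)
        # project out the centered covariate so the score is orthogonal
        resid = raw - cov_c * (cov_c @ raw) / (cov_c @ cov_c)
        resid = resid - resid.mean() + 1.0
        s = pd.Series(resid, index=idx)
        out = residualize(s, pd.DataFrame({"c": cov}, index=idx))
        np.testing.assert_allclose(out, s, atol=1e-10)

    def test_batch_shift_removed_and_mean_preserved(self, rng):
        n = 200
        idx = [f"s{i}" for i in range(n)]
        batch = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        s = pd.Series(1.0 + 0.07 * rng.standard_normal(n), index=idx)
        s[batch == "b"] += 0.5
        out = residualize(s, pd.DataFrame({"batch": batch}, index=idx))
        ga = out[batch == "a"].mean()
        gb = out[batch == "b"].mean()
        assert ga == pytest.approx(gb, abs=1e-10)
        assert out.mean() == pytest.approx(s.mean(), abs=1e-10)

    def test_collinear_design_named(self, rng):
        n = 50
        idx = [f"s{i}" for i in range(n)]
        x = rng.standard_normal(n)
        cov = pd.DataFrame({"x1": x, "x2": 2 * x}, index=idx)
        s = pd.Series(rng.standard_normal(n), index=idx)
        with pytest.raises(PacemeterError, match="x1|x2"):
            residualize(s, cov)


class TestAgeAcceleration:
    def test_perfect_clock_has_zero_residuals(self, rng):
        age = pd.Series(rng.uniform(30, 80, 50), index=range(50))
        resid = age_acceleration(age.copy(), age)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_age(self, rng):
        age = pd.Series(rng.uniform(30, 80, 200), index=range(200))
        clock = 0.9 * age + rng.standard_normal(200) * 4
        resid = age_acceleration(clock, age)
        assert abs(np.corrcoef(resid, age)[0, 1]) < 1e-10

    def test_planted_subgroup_offset_recovered(self, rng):
        n = 400
        age = pd.Series(rng.uniform(30, 80, n), index=range(n))
        flagged = np.arange(n) < 100
        noise_sd = 2.0
        clock = age + 3.0 * flagged + noise_sd * rng.standard_normal(n)
        resid = age_acceleration(clock, age)
        sub = resid[flagged]
        offset_est = sub.mean() - resid[~flagged].mean()
        se = noise_sd * np.sqrt(1 / 100 + 1 / 300)
        assert abs(offset_est - 3.0) < 2 * se + 0.3

    def test_constant_age_rejected(self):
        age = pd.Series([50.0, 50.0, 50.0])
        with pytest.raises(PacemeterError):
            age_acceleration(pd.Series([1.0, 2.0, 3.0]), age)


def test_probe_overlap_counts():
    a = WeightModel(0, pd.Series({"cg1": 1.0, "cg2": 1.0}))
    b = WeightModel(0, pd.Series({"cg2": 1.0, "cg3": 1.0}))
    c = WeightModel(0, pd.Series({"cg9": 1.0}))
    assert probe_overlap(a, b) == ["cg2"]
    assert probe_overlap(a, c) == []
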