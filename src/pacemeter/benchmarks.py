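"""End-to-end benchmark scenarios on synthetic cohorts.

Each function regenerates its inputs from a seed, runs the relevant part
of the pipeline, and returns the headline quantities as a flat dict.
These are the computations behind the repository's acceptance checks and
the ``scripts/acceptance.py`` report; problem sizes are chosen so the
whole set runs in minutes on one CPU (see docs/methods.md).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from . import synthetic, validation
from .io_core import BetaMatrix, WeightModel, read_weight_model
from .kdm import estimate_ba, fit_kdm
from .pace import composite_pace, fit_slope_matrix, standardize_slopes
from .scores import score
from .train import TrainConfig, bootstrap_cv, predict, train_elastic_net

SYNTHETIC_WEIGHTS_RESOURCE = "dunedinpoam46_synthetic_weights.csv"


def _sub_seed(seed: int, tag: int) -> int:
    """Derive a stable 31-bit sub-seed for one benchmark component."""
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2**31))


def pace_pipeline_metrics(seed: int, n_subjects: int = 500) -> dict[str, float]:
    """Default longitudinal cohort -> growth models -> pace composite.

    Reports the normalization constant (cohort mean of pace), the pace
    dispersion, truth-recovery correlations for mixed-model and
    per-subject-OLS slopes, and the pace-vs-latent-pace correlation.
    """
    cfg = synthetic.SimulationConfig(n_subjects=n_subjects, seed=_sub_seed(seed, 1))
    panel, truth = synthetic.simulate_longitudinal_biomarkers(cfg)
    mixed = fit_slope_matrix(panel, method="mixed")
    ols = fit_slope_matrix(panel, method="per_subject_ols")

    def mean_truth_corr(slopes: pd.DataFrame) -> float:
        return float(np.mean([
            slopes[c].corr(truth.slopes[c]) for c in truth.slopes.columns
        ]))

    std = standardize_slopes(mixed, truth.extras["orientation"])
    pace = composite_pace(std)
    common = pace.index.intersection(truth.pace.index)
    return {
        "pace_cohort_mean": float(pace.mean()),
        "pace_cohort_sd": float(pace.std(ddof=0)),
        "mixed_slope_truth_r": mean_truth_corr(mixed),
        "ols_slope_truth_r": mean_truth_corr(ols),
        "pace_truth_r": float(pace.loc[common].corr(truth.pace.loc[common])),
        "n_subjects": n_subjects,
    }


def published_model_metrics() -> dict[str, float]:
    """Parse the packaged 46-CpG weight table (synthetic stand-in for the
    published pace-of-aging methylation model) and report its size."""
    ref = resources.files("pacemeter").joinpath("data", SYNTHETIC_WEIGHTS_RESOURCE)
    with resources.as_file(ref) as path:
        model = read_weight_model(path)
    return {"published_model_n_cpgs": float(model.n_probes)}


def kdm_grid_oracle_metrics(seed: int, n_subjects: int = 100,
                            grid_step: float = 0.01) -> dict[str, float]:
    """Max deviation of the closed-form KDM estimator from a dense
    grid-search minimizer of the weighted least-squares objective."""
    ref, ages, _ = synthetic.simulate_kdm_reference(n=1000, seed=_sub_seed(seed, 2))
    model = fit_kdm(ref, ages)
    subs, sages, _ = synthetic.simulate_kdm_reference(
        n=n_subjects, seed=_sub_seed(seed, 3))
    ba = estimate_ba(subs, sages, model, estimator="uncorrected")
    q = model.params["q"].to_numpy()
    k = model.params["k"].to_numpy()
    s = model.params["s"].to_numpy()
    grid = np.arange(-20.0, 140.0, grid_step)
    X = subs[model.biomarker_ids].to_numpy()
    obj = (((X[:, None, :] - q - np.outer(grid, k)[None, :, :]) / s) ** 2).sum(2)
    mins = grid[obj.argmin(axis=1)]
    dev = float(np.max(np.abs(ba.table["ba_e"].to_numpy() - mins)))
    return {"kdm_grid_max_abs_dev": dev, "kdm_grid_step": grid_step,
            "n_subjects": n_subjects}


def score_oracle_metrics(seed: int, n_probes: int = 1000,
                         n_samples: int = 50) -> dict[str, float]:
    """Max deviation of vectorized scoring from a naive per-sample loop."""
    rng = np.random.default_rng([_sub_seed(seed, 4), 0x5C0])
    probes = [f"cg{i:06d}" for i in range(n_probes)]
    samples = [f"s{j:04d}" for j in range(n_samples)]
    beta = BetaMatrix(pd.DataFrame(rng.random((n_probes, n_samples)),
                                   index=probes, columns=samples))
    model = WeightModel(float(rng.normal()),
                        pd.Series(rng.normal(0, 0.3, n_probes), index=probes))
    fast = score(beta, model)["score"]
    dev = 0.0
    for sid in samples:
        naive = model.intercept + float(
            np.sum([model.weights[p] * beta.values.loc[p, sid] for p in probes]))
        dev = max(dev, abs(fast[sid] - naive))
    return {"score_loop_max_abs_dev": float(dev),
            "n_probes": n_probes, "n_samples": n_samples}


TRAIN_SCENARIO = dict(n_cpgs=2000, n_signal=20, effect_size=0.45)
BOOTSTRAP_SCENARIO = dict(n_cpgs=1000, n_signal=20, effect_size=0.45)


def _methylation_cohort(n: int, seed: int, layout_seed: int, **scenario):
    rng = np.random.default_rng([seed, 0xFA2])
    pace = pd.Series(1.0 + 0.38 * rng.standard_normal(n),
                     index=[f"s{i:05d}" for i in range(n)], name="pace")
    beta, truth = synthetic.simulate_methylation(
        pace, seed=seed, layout_seed=layout_seed, **scenario)
    return beta, pace, truth


def elastic_net_recovery_metrics(seed: int, n: int = 400) -> dict[str, float]:
    """Planted-CpG recovery of the elastic-net trainer (2000 CpGs, 20 planted)."""
    s = _sub_seed(seed, 5)
    beta, pace, truth = _methylation_cohort(n, s, s, **TRAIN_SCENARIO)
    res = train_elastic_net(beta, pace, TrainConfig(seed=s))
    selected = set(res.model.probe_ids)
    planted = set(truth.signal_cpgs)
    precision = len(selected & planted) / len(selected) if selected else 0.0
    return {
        "enet_selected_n": float(res.n_selected),
        "enet_planted_precision": float(precision),
        "enet_in_sample_r": float(res.in_sample_r),
        "n_samples": n,
    }


def bootstrap_oracle_metrics(seed: int, n: int = 500,
                             reps: int = 20) -> dict[str, float]:
    """Repeated 90/10 splits vs a large-sample oracle from the same
    population (10x training set, 10,000-sample test set)."""
    layout = _sub_seed(seed, 6)
    cfg = dict(n_folds=5, n_lambdas=30)
    beta, pace, _ = _methylation_cohort(n, _sub_seed(seed, 7), layout,
                                        **BOOTSTRAP_SCENARIO)
    rep = bootstrap_cv(beta, pace, reps=reps, test_fraction=0.10,
                       config=TrainConfig(seed=_sub_seed(seed, 8), **cfg))
    beta_big, pace_big, _ = _methylation_cohort(10 * n, _sub_seed(seed, 9),
                                                layout, **BOOTSTRAP_SCENARIO)
    big = train_elastic_net(beta_big, pace_big,
                            TrainConfig(seed=_sub_seed(seed, 10), **cfg))
    beta_test, pace_test, _ = _methylation_cohort(10000, _sub_seed(seed, 11),
                                                  layout, **BOOTSTRAP_SCENARIO)
    oracle_r = float(np.corrcoef(predict(big.model, beta_test), pace_test)[0, 1])
    return {
        "bootstrap_mean_oos_r": rep.mean_oos_r,
        "bootstrap_sd_oos_r": rep.sd_oos_r,
        "bootstrap_mean_in_sample_r": float(np.mean(rep.in_sample_r)),
        "bootstrap_score_pairwise_r": rep.score_pairwise_r,
        "oracle_oos_r": oracle_r,
        "n_samples": n,
        "reps": reps,
    }


def coverage_metrics(seed: int, reps: int = 100) -> dict[str, float]:
    """95% CI coverage of planted effects for the Cox, Poisson, and
    trial-interaction estimators over ``reps`` simulated datasets."""
    rng = np.random.default_rng([seed, 0xC0F])
    cox_hits = pois_hits = trial_hits = 0
    for _ in range(reps):
        s = int(rng.integers(0, 2**31 - 1))
        sc = pd.Series(1.0 + 0.07 * np.random.default_rng([s, 1]).standard_normal(600),
                       index=[f"s{i}" for i in range(600)])
        surv, _ = synthetic.simulate_survival(sc, log_hr_per_sd=0.25,
                                              censor_rate=0.3, seed=s)
        res = validation.cox_hr(surv["time"], surv["event"], surv["score"])
        cox_hits += res.effect.covers(float(np.exp(0.25)))

        rng2 = np.random.default_rng([s, 2])
        z = rng2.standard_normal(2000)
        lam = np.exp(np.log(1.5) + 0.15 * (z - z.mean()) / z.std(ddof=0))
        cnt = pd.Series(rng2.poisson(lam).astype(float),
                        index=[f"s{i}" for i in range(2000)])
        es = validation.poisson_irr(cnt, pd.Series(z, index=cnt.index))
        pois_hits += es.ci_low <= float(np.exp(0.15)) <= es.ci_high

        long, _ = synthetic.simulate_trial(n=220, interaction=-0.30, seed=s)
        tri = validation.trial_interaction_model(long)
        trial_hits += tri.interaction.covers(-0.30)
    return {
        "cox_hr_coverage": cox_hits / reps,
        "poisson_irr_coverage": pois_hits / reps,
        "trial_interaction_coverage": trial_hits / reps,
        "reps": reps,
    }


def null_calibration_metrics(seed: int, reps: int = 1000) -> dict[str, float]:
    """Null coverage of every validation estimator (see validation module)."""
    out = validation.null_calibration_suite(reps=reps, seed=_sub_seed(seed, 12))
    return {f"null_coverage_{k}": v for k, v in out.items()} | {"reps": reps}


def cross_sectional_metrics(seed: int, n: int = 2000) -> dict[str, float]:
    """Age-gradient scenario calibrated to a population age-score r of 0.11."""
    slope = synthetic.age_slope_for_r(0.11, (28.0, 95.0), 0.07)
    pheno, scores = synthetic.simulate_cross_sectional(
        n, age_slope=slope, noise_sd=0.07, seed=_sub_seed(seed, 13))
    es = validation.effect_size_r(scores, pheno["age"])
    return {"cross_sectional_age_r": es.estimate, "n_samples": n}
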