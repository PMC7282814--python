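"""Validation-design estimators: per-SD effect sizes for aging scores.

Each function standardizes the score internally, so every estimate reads
"per 1 SD of the score" and is invariant to affine rescaling of the raw
measure.  Confidence intervals are Wald-type at 95%; when a cluster
column is given (e.g. twin families), standard errors are
cluster-robust.  Designs covered: standardized linear regression
(Pearson-r scale), difference-score and residualized change, Poisson
incidence-rate ratios, Cox hazard ratios with +/-1 SD Kaplan-Meier
strata, subject-demeaned (fixed-effects) within-person change, ordered
group contrasts in Cohen's d, and the randomized-trial 3-way
condition x time x baseline-score mixed-model interaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

from .io_core import PacemeterError

Z95 = float(stats.norm.ppf(0.975))


@dataclass
class EffectSize:
    estimate: float
    ci_low: float
    ci_high: float
    se: float
    estimand: str
    n: int
    covariates: list[str] = field(default_factory=list)
    p_value: float | None = None
    extras: dict = field(default_factory=dict)

    def covers(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high

    def to_dict(self) -> dict:
        return {
            "estimand": self.estimand,
            "estimate": self.estimate,
            "ci": [self.ci_low, self.ci_high],
            "se": self.se,
            "n": self.n,
            "covariates": self.covariates,
            "p_value": self.p_value,
        }


def _zscore(x: np.ndarray, what: str) -> np.ndarray:
    sd = np.std(x, ddof=0)
    if sd == 0:
        raise PacemeterError(f"zero variance in {what}")
    return (x - np.mean(x)) / sd


def _covariate_matrix(covariates: pd.DataFrame | None, index) -> pd.DataFrame | None:
    if covariates is None or covariates.shape[1] == 0:
        return None
    cov = covariates.loc[index]
    parts = []
    for col in cov.columns:
        s = cov[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float))
        else:
            parts.append(pd.get_dummies(s, prefix=col, drop_first=True, dtype=float))
    return pd.concat(parts, axis=1)


def _ols_effect(
    y: np.ndarray,
    z: np.ndarray,
    covariates: pd.DataFrame | None,
    cluster: pd.Series | None,
    estimand: str,
) -> EffectSize:
    X = pd.DataFrame({"const": 1.0, "score": z})
    cov_names: list[str] = []
    if covariates is not None:
        for c in covariates.columns:
            X[c] = covariates[c].to_numpy()
        cov_names = list(covariates.columns)
    model = sm.OLS(y, X.to_numpy())
    if cluster is not None:
        fit = model.fit(cov_type="cluster", cov_kwds={"groups": np.asarray(cluster)})
    else:
        fit = model.fit()
    b = float(fit.params[1])
    se = float(fit.bse[1])
    ci = fit.conf_int()
    return EffectSize(
        estimate=b, ci_low=float(ci[1][0]), ci_high=float(ci[1][1]), se=se,
        estimand=estimand, n=len(y), covariates=cov_names,
        p_value=float(fit.pvalues[1]),
    )


def effect_size_r(
    outcome: pd.Series,
    score: pd.Series,
    covariates: pd.DataFrame | None = None,
    cluster: pd.Series | None = None,
) -> EffectSize:
    """Standardized regression coefficient interpretable as Pearson r.

    Outcome and score are both z-scored; with no covariates and no
    clustering the estimate equals the plain Pearson correlation.
    """
    outcome = pd.Series(outcome, dtype=float)
    score = pd.Series(score, dtype=float).loc[outcome.index]
    y = _zscore(outcome.to_numpy(), "outcome")
    z = _zscore(score.to_numpy(), "score")
    cov = _covariate_matrix(covariates, outcome.index)
    clu = cluster.loc[outcome.index] if cluster is not None else None
    return _ols_effect(y, z, cov, clu, "r")


def change_analysis(
    y_followup: pd.Series,
    y_baseline: pd.Series,
    score: pd.Series,
    mode: str = "difference",
    covariates: pd.DataFrame | None = None,
    cluster: pd.Series | None = None,
) -> EffectSize:
    """Change over follow-up regressed on the score.

    ``difference`` regresses (follow-up - baseline) on the score;
    ``residualized`` regresses the follow-up on score + baseline, reading
    off the score coefficient.  Both return per-SD standardized effects.
    """
    y_followup = pd.Series(y_followup, dtype=float)
    if len(y_followup) < 3:
        raise PacemeterError("change analysis needs n >= 3")
    y_baseline = pd.Series(y_baseline, dtype=float).loc[y_followup.index]
    score = pd.Series(score, dtype=float).loc[y_followup.index]
    if mode == "difference":
        diff = y_followup - y_baseline
        es = effect_size_r(diff, score, covariates, cluster)
        es.estimand = "r_difference"
        return es
    if mode == "residualized":
        base = pd.DataFrame({"baseline": _zscore(y_baseline.to_numpy(), "baseline")},
                            index=y_followup.index)
        cov = _covariate_matrix(covariates, y_followup.index)
        cov = base if cov is None else pd.concat([base, cov], axis=1)
        es = effect_size_r(y_followup, score, cov, cluster)
        es.estimand = "r_residualized"
        return es
    raise PacemeterError(f"unknown mode {mode!r}")


def poisson_irr(
    count_outcome: pd.Series,
    score: pd.Series,
    covariates: pd.DataFrame | None = None,
    cluster: pd.Series | None = None,
    robust: bool = True,
) -> EffectSize:
    """Incidence-rate ratio per 1 SD of the score from Poisson regression.

    Robust (HC1 or cluster) errors by default, so binary incident
    outcomes can also be modeled on the rate-ratio scale.
    """
    count_outcome = pd.Series(count_outcome, dtype=float)
    vals = count_outcome.to_numpy()
    if np.any(vals < 0) or np.any(vals != np.round(vals)):
        raise PacemeterError("count outcome must be non-negative integers")
    if np.all(vals == 0):
        raise PacemeterError("count outcome is all zero")
    score = pd.Series(score, dtype=float).loc[count_outcome.index]
    z = _zscore(score.to_numpy(), "score")
    X = pd.DataFrame({"const": 1.0, "score": z}, index=count_outcome.index)
    cov = _covariate_matrix(covariates, count_outcome.index)
    cov_names: list[str] = []
    if cov is not None:
        for c in cov.columns:
            X[c] = cov[c].to_numpy()
        cov_names = list(cov.columns)
    model = sm.GLM(vals, X.to_numpy(), family=sm.families.Poisson())
    if cluster is not None:
        fit = model.fit(cov_type="cluster",
                        cov_kwds={"groups": np.asarray(cluster.loc[count_outcome.index])})
    elif robust:
        fit = model.fit(cov_type="HC1")
    else:
        fit = model.fit()
    b, se = float(fit.params[1]), float(fit.bse[1])
    return EffectSize(
        estimate=float(np.exp(b)),
        ci_low=float(np.exp(b - Z95 * se)), ci_high=float(np.exp(b + Z95 * se)),
        se=se, estimand="IRR", n=len(vals), covariates=cov_names,
        p_value=float(fit.pvalues[1]), extras={"log_irr": b},
    )


@dataclass
class CoxResult:
    effect: EffectSize
    strata: pd.Series  # sample -> slow / average / fast
    km_curves: dict[str, pd.DataFrame]


def cox_hr(
    time: pd.Series,
    event: pd.Series,
    score: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> CoxResult:
    """Hazard ratio per 1 SD of the score, plus +/-1 SD Kaplan-Meier strata.

    Strata: *slow* at or below mean - 1 SD, *fast* at or above mean + 1 SD,
    *average* within 1 SD.
    """
    time = pd.Series(time, dtype=float)
    event = pd.Series(event).loc[time.index].astype(int)
    if (time <= 0).any():
        raise PacemeterError("event times must be positive")
    if event.sum() == 0:
        raise PacemeterError("no events observed")
    score = pd.Series(score, dtype=float).loc[time.index]
    z = _zscore(score.to_numpy(), "score")
    df = pd.DataFrame({"time": time.to_numpy(), "event": event.to_numpy(), "score": z},
                      index=time.index)
    cov_names: list[str] = []
    cov = _covariate_matrix(covariates, time.index)
    if cov is not None:
        for c in cov.columns:
            df[c] = cov[c].to_numpy()
        cov_names = list(cov.columns)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    b = float(cph.params_["score"])
    se = float(cph.standard_errors_["score"])
    effect = EffectSize(
        estimate=float(np.exp(b)),
        ci_low=float(np.exp(b - Z95 * se)), ci_high=float(np.exp(b + Z95 * se)),
        se=se, estimand="HR", n=len(df), covariates=cov_names,
        p_value=float(cph.summary.loc["score", "p"]), extras={"log_hr": b},
    )
    strata = pd.Series(
        np.where(z <= -1.0, "slow", np.where(z >= 1.0, "fast", "average")),
        index=time.index, name="stratum",
    )
    km_curves = {}
    for name in ("slow", "average", "fast"):
        mask = strata == name
        if mask.sum() == 0:
            continue
        km = KaplanMeierFitter()
        km.fit(time[mask], event_observed=event[mask], label=name)
        km_curves[name] = km.survival_function_
    return CoxResult(effect=effect, strata=strata, km_curves=km_curves)


def within_person_change(
    repeated_scores: pd.DataFrame,
    unit_years: float = 5.0,
    subject_col: str = "subject_id",
    time_col: str = "time_years",
    score_col: str = "score",
) -> EffectSize:
    """Within-subject (fixed-effects) slope of score on time.

    Subject means are swept out (the econometric within transformation),
    so stable between-person differences cannot confound the estimate;
    degrees of freedom are reduced accordingly.  The slope is rescaled to
    ``unit_years`` (default per 5 years).
    """
    df = repeated_scores
    counts = df.groupby(subject_col)[time_col].count()
    keep = counts[counts >= 2].index
    if len(keep) < 2:
        raise PacemeterError("need >=2 subjects with >=2 observations")
    df = df[df[subject_col].isin(keep)]
    g = df.groupby(subject_col)
    y = df[score_col] - g[score_col].transform("mean")
    x = df[time_col] - g[time_col].transform("mean")
    sxx = float(x @ x)
    if sxx == 0:
        raise PacemeterError("no within-subject time variation")
    b = float(x @ y) / sxx
    resid = y - b * x
    dof = len(df) - len(keep) - 1
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(sigma2 / sxx)
    t = stats.t.ppf(0.975, dof)
    est, lo, hi = (v * unit_years for v in (b, b - t * se, b + t * se))
    return EffectSize(
        estimate=est, ci_low=lo, ci_high=hi, se=se * unit_years,
        estimand=f"within_person_slope_per_{unit_years:g}y", n=len(df),
        p_value=float(2 * stats.t.sf(abs(b / se), dof)),
        extras={"n_subjects": len(keep), "slope_per_year": b},
    )


@dataclass
class GroupContrastResult:
    pairwise_d: dict[str, EffectSize]  # group label -> d vs reference
    trend: EffectSize


def group_contrast(
    score: pd.Series,
    group: pd.Series,
    order: list | None = None,
    cluster: pd.Series | None = None,
) -> GroupContrastResult:
    """Cohen's d of each group vs the first (reference), plus a linear trend.

    d divides the mean difference by the pooled SD of the two groups; its
    CI comes from a cluster-aware regression of the pooled-SD-scaled score
    on a group indicator, so twin/family structure widens it properly.
    """
    score = pd.Series(score, dtype=float)
    group = pd.Series(group).loc[score.index]
    levels = order if order is not None else sorted(group.unique())
    if len(levels) < 2:
        raise PacemeterError("need >=2 groups")
    counts = group.value_counts()
    small = [g for g in levels if counts.get(g, 0) < 2]
    if small:
        raise PacemeterError(f"groups with <2 members: {small}")
    ref = levels[0]
    out: dict[str, EffectSize] = {}
    for g in levels[1:]:
        mask = group.isin([ref, g])
        s = score[mask]
        grp = group[mask]
        n0, n1 = (grp == ref).sum(), (grp == g).sum()
        v0, v1 = s[grp == ref].var(ddof=1), s[grp == g].var(ddof=1)
        pooled = np.sqrt(((n0 - 1) * v0 + (n1 - 1) * v1) / (n0 + n1 - 2))
        if pooled == 0:
            raise PacemeterError(f"zero pooled SD for contrast {ref!r} vs {g!r}")
        ind = (grp == g).astype(float).to_numpy()
        clu = cluster.loc[s.index] if cluster is not None else None
        es = _ols_effect(s.to_numpy() / pooled, ind, None, clu, "cohens_d")
        es.n = int(n0 + n1)
        es.extras["groups"] = (ref, g)
        out[str(g)] = es
    codes = group.map({g: i for i, g in enumerate(levels)}).astype(float)
    trend = effect_size_r(score, codes, cluster=cluster)
    trend.estimand = "trend_r"
    return GroupContrastResult(pairwise_d=out, trend=trend)


@dataclass
class TrialInteractionResult:
    interaction: EffectSize  # 3-way condition x time x score coefficient
    control_slope_per_sd: EffectSize
    treatment_slope_per_sd: EffectSize
    predicted_slopes: dict[str, float]  # arm x fast/slow -> predicted slope
    random_slope: bool


def trial_interaction_model(
    long_data: pd.DataFrame,
    subject_col: str = "sample_id",
    time_col: str = "time_years",
    condition_col: str = "condition",
    score_col: str = "baseline_score",
    outcome_col: str = "kdm_ba",
    random_slope: bool = False,
) -> TrialInteractionResult:
    """Mixed-effects growth model with a condition x time x score interaction.

    Fits ``outcome ~ time * condition * z(score)`` with a random intercept
    per subject (optionally a random time slope); the 3-way coefficient is
    the difference between arms in how the time slope depends on baseline
    score (per SD).  Also reports the model-implied slopes at baseline
    score +/- 1 SD per arm (the trial-display contract).  A singular
    random-slope fit is retried with a random intercept only.
    """
    df = long_data.copy()
    cond = df[condition_col].astype(float)
    if set(cond.unique()) - {0.0, 1.0}:
        raise PacemeterError("condition must be binary 0/1")
    for arm in (0.0, 1.0):
        if df.loc[cond == arm, time_col].nunique() < 2:
            raise PacemeterError("each arm needs >=2 visit times")
    # standardize baseline score over subjects (not rows)
    per_subj = df.groupby(subject_col)[score_col].first()
    z_map = (per_subj - per_subj.mean()) / per_subj.std(ddof=0)
    df["_z"] = df[subject_col].map(z_map)
    df["_t"] = df[time_col].astype(float)
    df["_c"] = cond
    exog = pd.DataFrame(
        {
            "const": 1.0,
            "t": df["_t"],
            "c": df["_c"],
            "z": df["_z"],
            "t_c": df["_t"] * df["_c"],
            "t_z": df["_t"] * df["_z"],
            "c_z": df["_c"] * df["_z"],
            "t_c_z": df["_t"] * df["_c"] * df["_z"],
        }
    )
    used_random_slope = random_slope
    fit = None
    for try_slope in ([True, False] if random_slope else [False]):
        re_formula = "1 + _t" if try_slope else "1"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(
                df[outcome_col].to_numpy(), exog.to_numpy(),
                groups=df[subject_col].to_numpy(),
                exog_re=(exog[["const", "t"]].to_numpy() if try_slope
                         else exog[["const"]].to_numpy()),
            )
            try:
                fit = model.fit(reml=True, method="lbfgs")
            except (np.linalg.LinAlgError, ValueError):
                fit = None
        if fit is not None and fit.converged:
            used_random_slope = try_slope
            break
        warnings.warn("random-slope fit singular; refitting with random intercept only")
        used_random_slope = False
    if fit is None:
        raise PacemeterError("mixed model failed to converge")

    names = list(exog.columns)
    params = pd.Series(np.asarray(fit.fe_params), index=names)
    bse = pd.Series(np.asarray(fit.bse_fe), index=names)
    cov_fe = pd.DataFrame(np.asarray(fit.cov_params())[: len(names), : len(names)],
                          index=names, columns=names)

    def _wald(est: float, se: float, estimand: str) -> EffectSize:
        return EffectSize(
            estimate=float(est), ci_low=float(est - Z95 * se),
            ci_high=float(est + Z95 * se), se=float(se), estimand=estimand,
            n=int(df[subject_col].nunique()),
            p_value=float(2 * stats.norm.sf(abs(est / se))) if se > 0 else None,
        )

    b3 = _wald(params["t_c_z"], bse["t_c_z"], "trial_3way_interaction")
    ctrl = _wald(params["t_z"], bse["t_z"], "control_slope_per_sd")
    treat_est = params["t_z"] + params["t_c_z"]
    treat_se = np.sqrt(
        cov_fe.loc["t_z", "t_z"] + cov_fe.loc["t_c_z", "t_c_z"]
        + 2 * cov_fe.loc["t_z", "t_c_z"]
    )
    treat = _wald(treat_est, treat_se, "treatment_slope_per_sd")

    predicted = {}
    for arm_name, c in (("control", 0.0), ("treatment", 1.0)):
        for sd_name, zv in (("slow", -1.0), ("fast", 1.0)):
            slope = (
                params["t"] + params["t_c"] * c + params["t_z"] * zv
                + params["t_c_z"] * c * zv
            )
            predicted[f"{arm_name}_{sd_name}"] = float(slope)
    return TrialInteractionResult(
        interaction=b3, control_slope_per_sd=ctrl, treatment_slope_per_sd=treat,
        predicted_slopes=predicted, random_slope=used_random_slope,
    )


def null_calibration_suite(
    reps: int = 1000,
    n: int = 200,
    seed: int = 0,
    estimators: list[str] | None = None,
) -> dict[str, float]:
    """Fraction of simulated null datasets whose 95% CI covers the null.

    For each estimator, ``reps`` independent datasets are drawn with *no*
    planted effect and the estimator's CI is checked against its null
    value (0 for regression scales, 1 for IRR and HR).  A well-calibrated
    Wald interval should land near 0.95.  Returns estimator -> coverage.
    """
    from . import synthetic  # local import to avoid a cycle

    all_names = [
        "effect_size_r", "change_difference", "change_residualized",
        "poisson_irr", "cox_hr", "within_person_change", "group_contrast_d",
        "trial_interaction",
    ]
    names = estimators if estimators is not None else all_names
    rng = np.random.default_rng([seed, 0xCA1])
    cover = {name: 0 for name in names}
    idx = [f"s{i:04d}" for i in range(n)]
    for rep in range(reps):
        if "effect_size_r" in names:
            y = pd.Series(rng.standard_normal(n), index=idx)
            x = pd.Series(rng.standard_normal(n), index=idx)
            cover["effect_size_r"] += effect_size_r(y, x).covers(0.0)
        if "change_difference" in names or "change_residualized" in names:
            base = pd.Series(rng.standard_normal(n), index=idx)
            fol = 0.6 * base + pd.Series(0.8 * rng.standard_normal(n), index=idx)
            sc = pd.Series(rng.standard_normal(n), index=idx)
            if "change_difference" in names:
                cover["change_difference"] += change_analysis(
                    fol, base, sc, mode="difference").covers(0.0)
            if "change_residualized" in names:
                cover["change_residualized"] += change_analysis(
                    fol, base, sc, mode="residualized").covers(0.0)
        if "poisson_irr" in names:
            cnt = pd.Series(rng.poisson(1.5, n).astype(float), index=idx)
            sc = pd.Series(rng.standard_normal(n), index=idx)
            cover["poisson_irr"] += poisson_irr(cnt, sc).covers(1.0)
        if "cox_hr" in names:
            sc = pd.Series(1.0 + 0.07 * rng.standard_normal(n), index=idx)
            surv, _ = synthetic.simulate_survival(
                sc, log_hr_per_sd=0.0, censor_rate=0.3,
                seed=int(rng.integers(0, 2**31 - 1)))
            res = cox_hr(surv["time"], surv["event"], surv["score"])
            cover["cox_hr"] += res.effect.covers(1.0)
        if "within_person_change" in names:
            n_subj, n_visit = max(n // 4, 20), 4
            t = np.tile(np.arange(n_visit, dtype=float), n_subj)
            subj = np.repeat(np.arange(n_subj), n_visit)
            level = rng.standard_normal(n_subj)[subj]
            df = pd.DataFrame({
                "subject_id": subj, "time_years": t,
                "score": level + 0.1 * rng.standard_normal(len(t)),
            })
            cover["within_person_change"] += within_person_change(df).covers(0.0)
        if "group_contrast_d" in names:
            sc = pd.Series(rng.standard_normal(n), index=idx)
            grp = pd.Series(rng.integers(0, 3, n), index=idx)
            res = group_contrast(sc, grp)
            es = res.pairwise_d[str(sorted(grp.unique())[1])]
            cover["group_contrast_d"] += es.covers(0.0)
        if "trial_interaction" in names:
            long, _ = synthetic.simulate_trial(
                n=max(n // 2, 60), interaction=0.0, slope_per_sd_control=0.0,
                seed=int(rng.integers(0, 2**31 - 1)))
            res = trial_interaction_model(long)
            cover["trial_interaction"] += res.interaction.covers(0.0)
    return {k: v / reps for k, v in cover.items()}
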