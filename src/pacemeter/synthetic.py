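"""Synthetic cohorts with the statistical structure the pipeline assumes.

Every generator is a pure function of its arguments plus an integer seed,
so reruns are bit-identical.  Generated alongside each dataset is a
:class:`TruthRecord` holding the latent quantities (true pace, true
slopes, planted CpGs, planted hazards/interactions) that parameter-recovery
tests compare against.

The default longitudinal design mirrors a birth cohort measured at ages
26, 32 and 38 on 18 organ-system biomarkers.  Each subject carries a
latent *pace* (Gaussian, mean 1, SD 0.38) that loads on every biomarker's
rate of change; the loading and the idiosyncratic slope variance are set
so that the cross-biomarker slope correlation hits the configured target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .io_core import BetaMatrix, PacemeterError

DEFAULT_WAVE_AGES = (26.0, 32.0, 38.0)


@dataclass
class SimulationConfig:
    """Parameters of the longitudinal biomarker generator.

    ``slope_sd`` is the total between-subject SD of each biomarker's true
    rate of change (units/year); ``slope_correlation`` the target pairwise
    correlation of true slopes across biomarkers (the shared-pace share of
    slope variance); ``residual_sd`` the visit-level measurement noise;
    ``missing_wave_rate`` the fraction of subject-biomarker series that
    lose one random wave (leaving two), which is what lets the
    mixed-model BLUPs beat per-subject least squares.
    """

    n_subjects: int = 500
    wave_ages: tuple[float, ...] = DEFAULT_WAVE_AGES
    n_biomarkers: int = 18
    slope_sd: float = 0.1
    slope_correlation: float = 0.6
    residual_sd: float = 0.5
    intercept_sd: float = 1.0
    pace_sd: float = 0.38
    missing_wave_rate: float = 0.15
    orientation: np.ndarray | None = None  # +1 rises with aging, -1 falls
    seed: int = 0

    def __post_init__(self) -> None:
        ages = np.asarray(self.wave_ages, dtype=float)
        if len(ages) < 2 or np.any(np.diff(ages) <= 0):
            raise PacemeterError("wave_ages must be strictly increasing with >=2 waves")
        if not 0.0 <= self.slope_correlation <= 1.0:
            raise PacemeterError("slope_correlation must lie in [0, 1]")
        if min(self.slope_sd, self.residual_sd, self.intercept_sd, self.pace_sd) < 0:
            raise PacemeterError("standard deviations must be >= 0")
        if self.orientation is None:
            # alternate rising/falling markers so orientation logic is exercised
            self.orientation = np.where(np.arange(self.n_biomarkers) % 2 == 0, 1.0, -1.0)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.orientation.shape != (self.n_biomarkers,):
            raise PacemeterError("orientation must have one sign per biomarker")


@dataclass
class TruthRecord:
    """Latent ground truth saved by the generators for recovery tests."""

    pace: pd.Series | None = None  # subject -> true pace
    slopes: pd.DataFrame | None = None  # subject x biomarker true (oriented) slopes
    signal_cpgs: list[str] = field(default_factory=list)
    cpg_effects: pd.Series | None = None  # logit-shift per pace unit
    log_hr_per_sd: float | None = None
    trial_interaction: float | None = None
    extras: dict = field(default_factory=dict)


def _subject_ids(n: int) -> list[str]:
    return [f"s{i:04d}" for i in range(n)]


def simulate_longitudinal_biomarkers(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate a long-format biomarker panel with correlated random slopes.

    Returns ``(panel, truth)`` where ``panel`` has columns
    ``subject_id, biomarker_id, age, value`` and ``truth`` carries the
    per-subject latent pace and the true oriented slope matrix.
    """
    cfg = config
    if cfg.n_subjects < 2:
        raise PacemeterError("need at least 2 subjects")
    rng = np.random.default_rng([cfg.seed, 0xB10])
    subjects = _subject_ids(cfg.n_subjects)
    biomarkers = [f"bm{j:02d}" for j in range(cfg.n_biomarkers)]
    ages = np.asarray(cfg.wave_ages, dtype=float)
    n, m, w = cfg.n_subjects, cfg.n_biomarkers, len(ages)

    pace = 1.0 + cfg.pace_sd * rng.standard_normal(n)
    # per-biomarker mean rate of decline, deterministic and nonzero
    base_rate = 0.05 + 0.10 * (np.arange(m) / max(m - 1, 1))
    loading = np.sqrt(cfg.slope_correlation) * cfg.slope_sd / cfg.pace_sd if cfg.pace_sd > 0 else 0.0
    idio_sd = np.sqrt(1.0 - cfg.slope_correlation) * cfg.slope_sd

    raw_slopes = (
        base_rate[None, :]
        + loading * (pace[:, None] - 1.0)
        + idio_sd * rng.standard_normal((n, m))
    )
    slopes = raw_slopes * cfg.orientation[None, :]  # oriented: sign of observed change
    level = 10.0 + 2.0 * np.arange(m)  # per-biomarker baseline level
    intercepts = level[None, :] + cfg.intercept_sd * rng.standard_normal((n, m))

    age_c = ages - ages[0]
    values = (
        intercepts[:, :, None]
        + slopes[:, :, None] * age_c[None, None, :]
        + cfg.residual_sd * rng.standard_normal((n, m, w))
    )

    keep = np.ones((n, m, w), dtype=bool)
    if cfg.missing_wave_rate > 0 and w > 2:
        drop_series = rng.random((n, m)) < cfg.missing_wave_rate
        drop_wave = rng.integers(0, w, size=(n, m))
        ii, jj = np.nonzero(drop_series)
        keep[ii, jj, drop_wave[ii, jj]] = False

    si, bj, wk = np.nonzero(keep)
    panel = pd.DataFrame(
        {
            "subject_id": np.array(subjects)[si],
            "biomarker_id": np.array(biomarkers)[bj],
            "age": ages[wk],
            "value": values[si, bj, wk],
        }
    )
    truth = TruthRecord(
        pace=pd.Series(pace, index=subjects, name="pace"),
        slopes=pd.DataFrame(slopes, index=subjects, columns=biomarkers),
        extras={"orientation": pd.Series(cfg.orientation, index=biomarkers)},
    )
    return panel, truth


def simulate_methylation(
    pace: pd.Series,
    n_cpgs: int = 2000,
    n_signal: int = 20,
    effect_size: float = 0.45,
    logit_noise_sd: float = 0.5,
    seed: int = 0,
    layout_seed: int | None = None,
) -> tuple[BetaMatrix, TruthRecord]:
    """Beta matrix with a planted pace signal in ``n_signal`` CpGs.

    Betas are logit-normal: for signal CpG *c*,
    ``logit(beta) = mu_c +/- effect_size * (pace - 1) + noise``; null CpGs
    omit the pace term.  The default ``effect_size=0.45`` with
    ``logit_noise_sd=0.5`` and pace SD 0.38 yields a univariate
    beta-vs-pace correlation of roughly 0.3 per signal CpG.

    ``layout_seed`` fixes which CpGs carry signal (identities, effect
    signs, per-CpG baseline means) independently of the sampling noise in
    ``seed``, so that independent cohorts can be drawn from the *same*
    population — e.g. a large-sample oracle cohort for cross-validation
    checks.  It defaults to ``seed``.
    """
    pace = pd.Series(pace, dtype=float)
    if not np.all(np.isfinite(pace.to_numpy())):
        raise PacemeterError("pace values must be finite")
    if n_signal > n_cpgs:
        raise PacemeterError("n_signal cannot exceed n_cpgs")
    rng_layout = np.random.default_rng([(seed if layout_seed is None else layout_seed), 0xC9A])
    rng = np.random.default_rng([seed, 0xC9B])
    n = len(pace)
    cpg_ids = [f"cg{i:08d}" for i in range(n_cpgs)]
    signal_idx = rng_layout.choice(n_cpgs, size=n_signal, replace=False)
    signs = rng_layout.choice([-1.0, 1.0], size=n_signal)
    effects = np.zeros(n_cpgs)
    effects[signal_idx] = signs * effect_size

    mu = rng_layout.normal(0.0, 1.2, size=n_cpgs)
    centered = pace.to_numpy() - 1.0
    logits = (
        mu[:, None]
        + effects[:, None] * centered[None, :]
        + logit_noise_sd * rng.standard_normal((n_cpgs, n))
    )
    betas = special.expit(logits)
    bm = BetaMatrix(pd.DataFrame(betas, index=cpg_ids, columns=list(pace.index)))
    signal_ids = [cpg_ids[i] for i in sorted(signal_idx)]
    truth = TruthRecord(
        pace=pace,
        signal_cpgs=signal_ids,
        cpg_effects=pd.Series(effects[sorted(signal_idx)], index=signal_ids),
    )
    return bm, truth


def age_slope_for_r(
    target_r: float, age_range: tuple[float, float], noise_sd: float
) -> float:
    """Score-per-year slope giving population age-score correlation ``target_r``
    for uniformly distributed ages and Gaussian noise."""
    age_sd = (age_range[1] - age_range[0]) / np.sqrt(12.0)
    return target_r / np.sqrt(1.0 - target_r**2) * noise_sd / age_sd


def simulate_cross_sectional(
    n: int,
    age_range: tuple[float, float] = (28.0, 95.0),
    age_slope: float = 0.0,
    noise_sd: float = 0.07,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Age-graded cross-section: ages uniform, score = 1 + slope*(age-mean) + noise."""
    if age_range[1] <= age_range[0] and age_slope != 0.0:
        raise PacemeterError("degenerate age range with nonzero age_slope")
    rng = np.random.default_rng([seed, 0xA6E])
    ages = rng.uniform(age_range[0], age_range[1], size=n)
    scores = 1.0 + age_slope * (ages - ages.mean()) + noise_sd * rng.standard_normal(n)
    ids = _subject_ids(n)
    pheno = pd.DataFrame({"sample_id": ids, "age": ages}).set_index("sample_id")
    return pheno, pd.Series(scores, index=ids, name="score")


def expected_event_fraction(lambdas: np.ndarray, cmax: float) -> float:
    """P(T < C) for T ~ Exp(lambda_i), C ~ U(0, cmax), averaged over subjects."""
    lu = lambdas * cmax
    return float(np.mean(1.0 - (1.0 - np.exp(-lu)) / lu))


def simulate_survival(
    scores: pd.Series,
    log_hr_per_sd: float = 0.0,
    censor_rate: float = 0.3,
    base_hazard: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Exponential event times with hazard ``base_hazard * exp(log_hr * z)``
    and independent uniform censoring calibrated to ``censor_rate``."""
    if not 0.0 <= censor_rate < 1.0:
        raise PacemeterError("censor_rate must lie in [0, 1)")
    scores = pd.Series(scores, dtype=float)
    rng = np.random.default_rng([seed, 0x5E7])
    z = (scores - scores.mean()) / scores.std(ddof=0)
    lam = base_hazard * np.exp(log_hr_per_sd * z.to_numpy())
    t_event = rng.exponential(1.0 / lam)
    target = 1.0 - censor_rate
    if censor_rate == 0.0:
        t_censor = np.full(len(scores), np.inf)
    else:
        cmax = optimize.brentq(
            lambda u: expected_event_fraction(lam, u) - target, 1e-6 / base_hazard, 1e4 / base_hazard
        )
        t_censor = rng.uniform(0.0, cmax, size=len(scores))
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    pheno = pd.DataFrame(
        {"sample_id": list(scores.index), "time": time, "event": event, "score": scores.to_numpy()}
    ).set_index("sample_id")
    truth = TruthRecord(log_hr_per_sd=log_hr_per_sd)
    return pheno, truth


def simulate_trial(
    n: int = 220,
    allocation_ratio: tuple[int, int] = (2, 1),
    interaction: float = -0.30,
    control_slope: float = 0.71,
    treatment_slope: float = 0.11,
    slope_per_sd_control: float = 0.22,
    baseline_score_sd: float = 0.06,
    visit_months: tuple[float, ...] = (0.0, 12.0, 24.0),
    baseline_ba_sd: float = 7.0,
    visit_noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthRecord]:
    """2:1 randomized trial of a geroprotector, long format.

    Each subject has a baseline methylation pace score and a biological-age
    trajectory over the visits.  In the control arm the BA slope rises with
    baseline score (``slope_per_sd_control`` years/year per SD); in the
    treatment arm that dependence is shifted by ``interaction`` (the planted
    3-way condition x time x score coefficient).  Defaults echo a 220-person
    caloric-restriction trial with visits at months 0/12/24.
    """
    a, b = allocation_ratio
    n_treat = round(n * a / (a + b))
    n_ctrl = n - n_treat
    if min(n_treat, n_ctrl) < 2:
        raise PacemeterError("n too small to fill both arms")
    rng = np.random.default_rng([seed, 0x7A1])
    ids = _subject_ids(n)
    condition = np.array([1] * n_treat + [0] * n_ctrl)
    rng.shuffle(condition)
    score = 1.0 + baseline_score_sd * rng.standard_normal(n)
    z = (score - score.mean()) / score.std(ddof=0)
    slope = np.where(
        condition == 1,
        treatment_slope + (slope_per_sd_control + interaction) * z,
        control_slope + slope_per_sd_control * z,
    )
    baseline_ba = 38.0 + baseline_ba_sd * rng.standard_normal(n)
    rows = []
    for t_months in visit_months:
        t_years = t_months / 12.0
        ba = baseline_ba + slope * t_years + visit_noise_sd * rng.standard_normal(n)
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": ids,
                    "visit_months": t_months,
                    "time_years": t_years,
                    "condition": condition,
                    "baseline_score": score,
                    "kdm_ba": ba,
                }
            )
        )
    long = pd.concat(rows, ignore_index=True)
    truth = TruthRecord(
        trial_interaction=interaction,
        extras={"control_slope": control_slope, "slope_per_sd_control": slope_per_sd_control},
    )
    return long, truth


def simulate_kdm_reference(
    n: int = 1000,
    biomarkers: dict[str, tuple[float, float, float]] | None = None,
    age_range: tuple[float, float] = (30.0, 75.0),
    ba_sd: float = 5.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, dict[str, tuple[float, float, float]]]:
    """Reference sample for Klemera-Doubal calibration.

    ``biomarkers`` maps id -> (q, k, s): biomarker = q + k*BA + N(0, s^2),
    where the latent biological age BA = chronological age + N(0, ba_sd^2).
    ``ba_sd`` (years) is the between-person dispersion of biological about
    chronological age that the corrected estimator's ``s2_BA`` term
    targets; set it to 0 to generate pure age-indexed biomarkers.
    The default panel has 8 markers with heterogeneous slopes and noise,
    echoing a blood-chemistry/blood-pressure/lung-function panel.
    """
    if biomarkers is None:
        rng0 = np.random.default_rng(12345)  # fixed panel definition, not per-draw
        biomarkers = {
            f"kbm{j}": (
                float(rng0.uniform(20, 120)),
                float(rng0.uniform(0.2, 1.2) * (1 if j % 4 else -1)),
                float(rng0.uniform(3, 12)),
            )
            for j in range(8)
        }
    rng = np.random.default_rng([seed, 0x4D1])
    ages = rng.uniform(age_range[0], age_range[1], size=n)
    latent_ba = ages + ba_sd * rng.standard_normal(n)
    data = {"age": ages}
    for name, (q, k, s) in biomarkers.items():
        data[name] = q + k * latent_ba + s * rng.standard_normal(n)
    df = pd.DataFrame(data, index=_subject_ids(n))
    df.index.name = "sample_id"
    return df.drop(columns="age"), df["age"], biomarkers
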