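"""Pace of Aging: from a longitudinal biomarker panel to a unit-mean composite.

The pipeline is the classic three-step construction: (1) fit a
random-intercept/random-slope growth model per biomarker and extract each
subject's posterior (BLUP) slope — or, alternatively, independent
per-subject least-squares slopes; (2) orient every slope so that positive
means aging-consistent change and z-score each biomarker column; (3)
average the oriented z-scored slopes per subject and rescale the composite
affinely so the cohort mean is exactly 1 "year of physiological change per
calendar year" (dispersion set by ``scale_sd``, default 0.38).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .io_core import PacemeterError

logger = logging.getLogger(__name__)

PANEL_COLUMNS = ("subject_id", "biomarker_id", "age", "value")


def _check_panel(panel: pd.DataFrame) -> None:
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise PacemeterError(f"panel lacks columns: {missing}")
    if panel.duplicated(["subject_id", "biomarker_id", "age"]).any():
        raise PacemeterError("duplicate (subject, biomarker, age) rows in panel")


def _ols_slopes(sub: pd.DataFrame) -> pd.Series:
    """Independent least-squares slope per subject (NaN below 2 distinct ages)."""
    out = {}
    for sid, grp in sub.groupby("subject_id", sort=False):
        ages = grp["age"].to_numpy(dtype=float)
        if len(np.unique(ages)) < 2:
            out[sid] = np.nan
            continue
        x = ages - ages.mean()
        y = grp["value"].to_numpy(dtype=float)
        out[sid] = float(x @ (y - y.mean()) / (x @ x))
    return pd.Series(out, name="slope")

def fit_growth_model(
    panel: pd.DataFrame, biomarker_id: str, method: str = "mixed"
) -> pd.Series:
    """Per-subject rate of change for one biomarker.

    ``method="mixed"`` fits a random-intercept + random-slope model on age
    (centered at the first wave) and returns fixed + BLUP slopes, shrunk
    toward the cohort mean rate; subjects observed at fewer than two
    distinct ages get NaN.  ``method="per_subject_ols"`` fits each subject
    independently.  A singular or non-converged mixed fit falls back to
    per-subject OLS with a logged warning.
    """
    _check_panel(panel)
    sub = panel[panel["biomarker_id"] == biomarker_id]
    if sub.empty:
        raise PacemeterError(f"biomarker {biomarker_id!r} not present in panel")
    if sub.groupby("subject_id")["age"].nunique().max() < 2:
        raise PacemeterError(f"biomarker {biomarker_id!r} has no subject with >=2 waves")

    if method == "per_subject_ols":
        return _ols_slopes(sub)
    if method != "mixed":
        raise PacemeterError(f"unknown method {method!r}")
    if sub["subject_id"].nunique() < 10:
        raise PacemeterError("mixed method needs >=10 subjects")

    df = sub.copy()
    df["age_c"] = df["age"] - df["age"].min()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "value ~ age_c", df, groups=df["subject_id"], re_formula="~age_c"
            )
            fit = model.fit(reml=True, method="lbfgs")
        if not fit.converged:
            raise np.linalg.LinAlgError("mixed model did not converge")
        fixed_slope = float(fit.fe_params["age_c"])
        re = fit.random_effects
        slopes = {sid: fixed_slope + float(eff.get("age_c", 0.0)) for sid, eff in re.items()}
    except (np.linalg.LinAlgError, ValueError) as exc:
        logger.warning(
            "mixed fit failed for %s (%s); falling back to per-subject OLS",
            biomarker_id, exc,
        )
        return _ols_slopes(sub)

    n_ages = sub.groupby("subject_id")["age"].nunique()
    out = pd.Series(slopes, name="slope")
    out[n_ages[n_ages < 2].index] = np.nan
    return out


def fit_slope_matrix(panel: pd.DataFrame, method: str = "mixed") -> pd.DataFrame:
    """Slope matrix (subjects x biomarkers) across every biomarker in the panel."""
    _check_panel(panel)
    cols = {
        bm: fit_growth_model(panel, bm, method=method)
        for bm in panel["biomarker_id"].unique()
    }
    return pd.DataFrame(cols)


def standardize_slopes(
    slopes: pd.DataFrame, orientation: dict[str, float] | pd.Series
) -> pd.DataFrame:
    """Orient each biomarker column (+1 keeps sign, -1 flips) then z-score it.

    After orientation a positive value means faster-than-average
    aging-direction change.  Raises on a zero-variance column, naming it.
    """
    orientation = pd.Series(orientation, dtype=float)
    missing = [c for c in slopes.columns if c not in orientation.index]
    if missing:
        raise PacemeterError(f"orientation missing for biomarkers: {missing}")
    out = {}
    for col in slopes.columns:
        v = slopes[col] * orientation[col]
        sd = v.std(ddof=0)
        if not np.isfinite(sd) or sd == 0:
            raise PacemeterError(f"zero-variance slope column: {col!r}")
        out[col] = (v - v.mean()) / sd
    return pd.DataFrame(out)


def composite_pace(
    std_slopes: pd.DataFrame,
    min_biomarkers: int | None = None,
    scale_sd: float = 0.38,
) -> pd.Series:
    """Unit-weighted mean of standardized slopes, affinely rescaled to mean 1.

    Subjects with fewer than ``min_biomarkers`` non-missing slopes
    (default: half the panel) are dropped.  The returned pace has cohort
    mean exactly 1 and SD ``scale_sd``; if all subjects have identical
    composites every pace is exactly 1.
    """
    if min_biomarkers is None:
        min_biomarkers = int(np.ceil(std_slopes.shape[1] / 2))
    coverage = std_slopes.notna().sum(axis=1)
    kept = std_slopes.loc[coverage >= min_biomarkers]
    if kept.empty:
        raise PacemeterError("all subjects excluded by the minimum-coverage rule")
    composite = kept.mean(axis=1, skipna=True)
    sd = composite.std(ddof=0)
    # variance at rounding level counts as zero (cancellation guard)
    if sd <= 1e-12 * max(1.0, float(composite.abs().max())):
        pace = pd.Series(1.0, index=composite.index)
    else:
        pace = 1.0 + (composite - composite.mean()) / sd * scale_sd
        pace = pace - (pace.mean() - 1.0)  # pin the mean exactly
    pace.name = "pace"
    return pace


def pace_of_aging(
    panel: pd.DataFrame,
    orientation: dict[str, float] | pd.Series | None = None,
    method: str = "mixed",
    min_biomarkers: int | None = None,
    scale_sd: float = 0.38,
) -> pd.Series:
    """End-to-end: growth models -> orientation/z-scoring -> composite.

    When ``orientation`` is omitted, a data-driven fallback signs each
    biomarker by its loading on the leading eigenvector of the slope
    correlation matrix — the shared-pace axis — with the global sign fixed
    so a majority of biomarkers come out positive.  The global aging
    direction is not identifiable from slopes alone, so supplying known
    decline directions is always preferable.
    """
    slopes = fit_slope_matrix(panel, method=method)
    if orientation is None:
        corr = slopes.corr().to_numpy()  # pairwise-complete
        eigvals, eigvecs = np.linalg.eigh(corr)
        lead = eigvecs[:, -1]
        if np.sum(lead > 0) < len(lead) / 2:
            lead = -lead
        orientation = pd.Series(np.where(lead >= 0, 1.0, -1.0), index=slopes.columns)
    std = standardize_slopes(slopes, orientation)
    return composite_pace(std, min_biomarkers=min_biomarkers, scale_sd=scale_sd)
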