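"""Klemera-Doubal biological age (KDM BA).

Calibration regresses each biomarker *x_j* on chronological age in a
reference sample, giving intercept ``q_j``, slope ``k_j`` and RMSE
``s_j``.  The uncorrected estimator for a subject with biomarkers ``x`` is
the precision-weighted least-squares age::

    BA_E = sum_j (x_j - q_j) k_j / s_j^2  /  sum_j k_j^2 / s_j^2

i.e. the minimizer over t of sum_j ((x_j - q_j - k_j t) / s_j)^2.  The
corrected estimator treats chronological age (CA) as one more noisy
indicator of biological age with variance ``s2_BA``::

    BA_EC = (sum_j (x_j - q_j) k_j / s_j^2 + CA / s2_BA)
            / (sum_j k_j^2 / s_j^2 + 1 / s2_BA)

``s2_BA`` is estimated by the method of moments: the variance of
``BA_E - CA`` in the reference sample minus the dispersion expected from
measurement noise alone,
``(1 - r_char^2) / r_char^2 * (CA_max - CA_min)^2 / (12 m)``, where
``r_char`` is the characteristic correlation of the m-biomarker battery.
A non-positive estimate falls back to the uncorrected estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import PacemeterError

logger = logging.getLogger(__name__)


@dataclass
class KDMModel:
    """Per-biomarker (q, k, s, r) calibration plus the BA variance term."""

    params: pd.DataFrame  # index biomarker, columns q, k, s, r
    s2_ba: float
    age_range: tuple[float, float]
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.params) < 2:
            raise PacemeterError("KDM model needs at least 2 biomarkers")
        if (self.params["s"] <= 0).any():
            raise PacemeterError("all retained biomarkers must have s > 0")

    @property
    def biomarker_ids(self) -> list[str]:
        return list(self.params.index)


@dataclass
class BioAgeTable:
    table: pd.DataFrame  # index sample, columns kdm_ba, ba_e, advancement


def _characteristic_r(r: np.ndarray) -> float:
    # r_char = sum(r^2 / sqrt(1-r^2)) / sum(r / sqrt(1-r^2)), on |r|
    r = np.abs(r)
    r = np.clip(r, 1e-12, 1 - 1e-12)
    w = r / np.sqrt(1.0 - r**2)
    return float(np.sum(r * w) / np.sum(w))


def fit_kdm(
    reference: pd.DataFrame,
    ages: pd.Series,
    biomarker_ids: list[str] | None = None,
    min_abs_r: float | None = None,
) -> KDMModel:
    """Calibrate per-biomarker age regressions on a reference sample.

    Biomarkers whose age correlation falls below ``min_abs_r`` (default
    ``2 / sqrt(n)``, the null band) are dropped with a warning.  Needs at
    least 30 reference subjects.
    """
    ages = pd.Series(ages, dtype=float).loc[reference.index]
    n = len(reference)
    if n < 30:
        raise PacemeterError("KDM calibration needs >= 30 reference subjects")
    if biomarker_ids is None:
        biomarker_ids = list(reference.columns)
    if min_abs_r is None:
        min_abs_r = 2.0 / np.sqrt(n)
    a = ages.to_numpy()
    rows, dropped = {}, []
    for bm in biomarker_ids:
        x = reference[bm].to_numpy(dtype=float)
        res = stats.linregress(a, x)
        if abs(res.rvalue) <= min_abs_r:
            dropped.append(bm)
            logger.warning("dropping biomarker %r: age correlation %.3f below %.3f",
                           bm, res.rvalue, min_abs_r)
            continue
        resid = x - (res.intercept + res.slope * a)
        s = float(np.sqrt(np.mean(resid**2)))
        rows[bm] = {"q": float(res.intercept), "k": float(res.slope), "s": s,
                    "r": float(res.rvalue)}
    if not rows:
        raise PacemeterError("all biomarkers dropped during KDM calibration")
    params = pd.DataFrame.from_dict(rows, orient="index")

    # uncorrected BA on the reference itself -> method-of-moments s2_BA
    ba_e = _ba_e(reference[list(params.index)], params)
    diff = ba_e.to_numpy() - a
    m = len(params)
    r_char = _characteristic_r(params["r"].to_numpy())
    noise_term = (1.0 - r_char**2) / r_char**2 * (a.max() - a.min()) ** 2 / (12.0 * m)
    s2_ba = float(np.var(diff, ddof=0) - noise_term)
    if s2_ba <= 0:
        logger.warning("non-positive s2_BA (%.3f); corrected estimator will fall back "
                       "to the uncorrected form", s2_ba)
    return KDMModel(params=params, s2_ba=s2_ba,
                    age_range=(float(a.min()), float(a.max())), dropped=dropped)


def _ba_e(x: pd.DataFrame, params: pd.DataFrame) -> pd.Series:
    q = params["q"].to_numpy()
    k = params["k"].to_numpy()
    s2 = params["s"].to_numpy() ** 2
    denom = np.sum(k**2 / s2)
    if denom == 0:
        raise PacemeterError("all KDM slopes are zero")
    num = (x.to_numpy(dtype=float) - q) @ (k / s2)
    return pd.Series(num / denom, index=x.index, name="ba_e")


def estimate_ba(
    subjects: pd.DataFrame,
    chron_age: pd.Series,
    model: KDMModel,
    estimator: str = "corrected",
) -> BioAgeTable:
    """Biological age and advancement (BA - CA) per subject.

    Subjects missing any retained biomarker are skipped with a warning.
    ``estimator`` is ``"corrected"`` (default; shrinks toward CA using
    ``s2_BA``) or ``"uncorrected"``.
    """
    if estimator not in ("corrected", "uncorrected"):
        raise PacemeterError(f"unknown estimator {estimator!r}")
    chron_age = pd.Series(chron_age, dtype=float).loc[subjects.index]
    need = model.biomarker_ids
    missing_cols = [b for b in need if b not in subjects.columns]
    if missing_cols:
        raise PacemeterError(f"subject table lacks biomarkers: {missing_cols}")
    x = subjects[need]
    complete = x.notna().all(axis=1)
    if not complete.all():
        logger.warning("skipping %d subjects with missing biomarkers", (~complete).sum())
    x = x.loc[complete]
    ca = chron_age.loc[complete].to_numpy()

    ba_e = _ba_e(x, model.params)
    if estimator == "corrected" and model.s2_ba > 0:
        k = model.params["k"].to_numpy()
        s2 = model.params["s"].to_numpy() ** 2
        q = model.params["q"].to_numpy()
        num = (x.to_numpy(dtype=float) - q) @ (k / s2) + ca / model.s2_ba
        den = np.sum(k**2 / s2) + 1.0 / model.s2_ba
        ba = num / den
    else:
        ba = ba_e.to_numpy()
    table = pd.DataFrame(
        {"kdm_ba": ba, "ba_e": ba_e.to_numpy(), "advancement": ba - ca},
        index=x.index,
    )
    return BioAgeTable(table)
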