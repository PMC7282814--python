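"""Apply CpG weight models to beta matrices; adjust and residualize scores.

Covers the scoring-time concerns the training step leaves open: probes
missing from the target array (fail / cohort-mean impute / reference
impute), the piecewise-log age calibration some chronological-age clocks
use, batch residualization that preserves the score's scale, and the
age-acceleration residuals used to compare rate and state measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import BetaMatrix, PacemeterError, WeightModel

MISSING_WARN_FRACTION = 0.05


@dataclass
class ClockCalibration:
    """Invertible transform from raw linear score to reported units.

    ``kind="identity"`` returns the raw score.  ``kind="anti_log_linear"``
    is the adult-age piecewise-log transform used by multi-tissue
    chronological clocks: raw values below 0 map as
    ``(adult_age + 1) * exp(raw) - 1``, values above as
    ``(adult_age + 1) * raw + adult_age``.
    """

    kind: str = "identity"
    adult_age: float = 20.0

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "anti_log_linear"):
            raise PacemeterError(f"unknown calibration kind {self.kind!r}")

    def apply(self, raw: np.ndarray) -> np.ndarray:
        raw = np.asarray(raw, dtype=float)
        if self.kind == "identity":
            return raw
        a = self.adult_age
        return np.where(raw < 0, (a + 1.0) * np.exp(raw) - 1.0, (a + 1.0) * raw + a)

    def invert(self, value: np.ndarray) -> np.ndarray:
        value = np.asarray(value, dtype=float)
        if self.kind == "identity":
            return value
        a = self.adult_age
        return np.where(value < a, np.log((value + 1.0) / (a + 1.0)), (value - a) / (a + 1.0))

    @classmethod
    def from_meta(cls, meta: dict) -> "ClockCalibration":
        cal = meta.get("calibration", {})
        return cls(
            kind=cal.get("kind", "identity"),
            adult_age=float(cal.get("adult_age", 20.0)),
        )


def score(
    beta: BetaMatrix,
    model: WeightModel,
    missing_policy: str = "mean_impute",
    calibration: ClockCalibration | None = None,
    reference: pd.Series | None = None,
    name: str = "score",
) -> pd.DataFrame:
    """Linear methylation score per sample.

    raw = intercept + sum over model probes of weight * beta, after the
    missing-value policy fills gaps:

    * ``fail`` — any missing model probe or cell raises, listing probes;
    * ``mean_impute`` — missing cells take the probe's cohort mean
      (probes entirely absent from the matrix cannot be mean-imputed and
      raise);
    * ``reference_impute`` — absent probes and missing cells take values
      from the supplied ``reference`` series (probe -> beta).

    Returns a DataFrame indexed by sample with columns ``<name>`` and
    ``<name>_n_imputed``.  The calibration transform, when given, is
    applied last.
    """
    if missing_policy not in ("fail", "mean_impute", "reference_impute"):
        raise PacemeterError(f"unknown missing_policy {missing_policy!r}")
    probes = model.probe_ids
    present = [p for p in probes if p in beta.values.index]
    absent = [p for p in probes if p not in beta.values.index]
    if model.n_probes and not present:
        raise PacemeterError("all model probes are missing from the beta matrix")

    sub = beta.values.reindex(probes)  # probes x samples, absent rows all-NaN
    n_missing_cells = sub.isna().sum(axis=0)  # per sample

    if missing_policy == "fail":
        bad = sub.index[sub.isna().any(axis=1)].tolist()
        if bad:
            raise PacemeterError(f"missing model probes/cells under 'fail' policy: {bad[:10]}")
        filled = sub
    elif missing_policy == "mean_impute":
        if absent:
            raise PacemeterError(
                "probes absent from the matrix cannot be cohort-mean imputed "
                f"(use reference_impute): {absent[:10]}"
            )
        means = sub.mean(axis=1, skipna=True)
        all_nan = means.index[means.isna()].tolist()
        if all_nan:
            raise PacemeterError(f"model probes with no observed values: {all_nan[:10]}")
        filled = sub.apply(lambda row: row.fillna(means[row.name]), axis=1)
    else:
        if reference is None:
            raise PacemeterError("reference_impute requires a reference series")
        reference = pd.Series(reference, dtype=float)
        uncovered = [p for p in probes if p not in reference.index]
        missing_rows = sub.isna().any(axis=1)
        need = [p for p in sub.index[missing_rows] if p in uncovered]
        if need:
            raise PacemeterError(f"reference lacks values for probes: {need[:10]}")
        filled = sub.copy()
        for p in sub.index[missing_rows]:
            filled.loc[p] = filled.loc[p].fillna(reference[p])

    frac = n_missing_cells.max() / max(model.n_probes, 1)
    if frac > MISSING_WARN_FRACTION:
        warnings.warn(
            f"{frac:.1%} of model probes imputed for at least one sample",
            stacklevel=2,
        )
    w = model.weights.reindex(filled.index).to_numpy()
    raw = model.intercept + w @ filled.to_numpy() if model.n_probes else np.full(
        beta.n_samples, model.intercept
    )
    if calibration is not None:
        raw = calibration.apply(raw)
    return pd.DataFrame(
        {name: raw, f"{name}_n_imputed": n_missing_cells.to_numpy()},
        index=beta.sample_ids,
    )


def _design_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix with intercept; categoricals dummy-coded."""
    parts = [pd.Series(1.0, index=covariates.index, name="const")]
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float))
        else:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.extend(dummies[c] for c in dummies.columns)
    return pd.concat(parts, axis=1)


def residualize(scores: pd.Series, covariates: pd.DataFrame) -> pd.Series:
    """Residuals of score on covariates, grand mean added back.

    Keeps the score on its original scale (units survive batch
    adjustment).  Raises on a rank-deficient design, naming candidate
    collinear columns.
    """
    scores = pd.Series(scores, dtype=float)
    covariates = covariates.loc[scores.index]
    X = _design_matrix(covariates)
    Xv = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        # identify columns whose removal restores full rank
        collinear = [
            X.columns[j]
            for j in range(1, Xv.shape[1])
            if np.linalg.matrix_rank(np.delete(Xv, j, axis=1)) == rank
        ]
        raise PacemeterError(f"rank-deficient design; collinear columns: {collinear}")
    coef, *_ = np.linalg.lstsq(Xv, scores.to_numpy(), rcond=None)
    resid = scores.to_numpy() - Xv @ coef
    out = pd.Series(resid + scores.mean(), index=scores.index, name=scores.name)
    return out


def age_acceleration(clock_scores: pd.Series, chron_age: pd.Series) -> pd.Series:
    """Residuals of a clock on chronological age (the acceleration measure)."""
    clock_scores = pd.Series(clock_scores, dtype=float)
    chron_age = pd.Series(chron_age, dtype=float).loc[clock_scores.index]
    if len(clock_scores) < 3:
        raise PacemeterError("age_acceleration needs >=3 samples")
    if chron_age.std(ddof=0) == 0:
        raise PacemeterError("chronological age is constant")
    x = chron_age.to_numpy()
    y = clock_scores.to_numpy()
    slope = np.cov(x, y, ddof=0)[0, 1] / np.var(x)
    resid = y - (y.mean() + slope * (x - x.mean()))
    return pd.Series(resid, index=clock_scores.index, name="age_acceleration")


def probe_overlap(model_a: WeightModel, model_b: WeightModel) -> list[str]:
    """CpGs shared by two weight models (expected empty for a rate measure
    vs the chronological clocks)."""
    return sorted(set(model_a.probe_ids) & set(model_b.probe_ids))
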