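"""Elastic-net distillation of Pace of Aging into a CpG weight model.

The trainer regresses the longitudinal pace composite on the beta matrix
with an elastic net (mixing parameter ``alpha`` = 0.5 by default, i.e. an
even L1/L2 blend) and exports the nonzero coefficients, mapped back to the
raw beta scale, as a :class:`~pacemeter.io_core.WeightModel` that can be
applied directly to new beta matrices.  Penalty strength is chosen by
k-fold cross-validation (minimum mean error by default, or the
one-standard-error rule).  ``bootstrap_cv`` repeats train/test splits to
estimate the out-of-sample correlation between the methylation score and
the measured pace, mirroring repeated 90/10 cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .io_core import BetaMatrix, PacemeterError, ProbeList, WeightModel, harmonize_probes


@dataclass
class TrainConfig:
    alpha: float = 0.5  # elastic-net mixing (1 = lasso, 0 = ridge)
    lambda_rule: str = "1se"  # or "cv_min"
    n_folds: int = 10
    n_lambdas: int = 50
    seed: int = 0
    probe_filter: ProbeList | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise PacemeterError("alpha must lie in [0, 1]")
        if self.n_folds < 2:
            raise PacemeterError("n_folds must be >= 2")
        if self.lambda_rule not in ("cv_min", "1se"):
            raise PacemeterError(f"unknown lambda_rule {self.lambda_rule!r}")


@dataclass
class TrainResult:
    model: WeightModel
    in_sample_r: float
    lambda_: float
    n_selected: int


@dataclass
class BootstrapReport:
    """Summary of repeated train/test splits.

    ``oos_r`` holds one held-out predicted-vs-measured correlation per
    repetition; ``n_selected`` the per-repetition CpG counts;
    ``score_pairwise_r`` the mean pairwise correlation among the
    repetition-specific scores computed on the full cohort.
    """

    oos_r: np.ndarray
    in_sample_r: np.ndarray
    n_selected: np.ndarray
    score_pairwise_r: float
    test_fraction: float
    extras: dict = field(default_factory=dict)

    @property
    def mean_oos_r(self) -> float:
        return float(np.mean(self.oos_r))

    @property
    def sd_oos_r(self) -> float:
        return float(np.std(self.oos_r, ddof=1))


def _aligned_xy(beta: BetaMatrix, pace: pd.Series, config: TrainConfig):
    if config.probe_filter is not None:
        beta = harmonize_probes(beta, config.probe_filter)
    pace = pd.Series(pace, dtype=float)
    common = [s for s in beta.sample_ids if s in pace.index]
    if not common:
        raise PacemeterError("beta matrix and pace share no samples")
    X = beta.values[common].to_numpy(dtype=float).T  # samples x probes
    if np.isnan(X).any():
        raise PacemeterError("training requires a complete beta matrix (impute first)")
    y = pace.loc[common].to_numpy(dtype=float)
    return X, y, list(beta.values.index), common


def _fit_enet(X: np.ndarray, y: np.ndarray, config: TrainConfig):
    """CV-tuned elastic net on standardized predictors.

    Returns (weights on raw scale, intercept, lambda).  sklearn's
    ``alpha`` is the penalty strength (lambda here); the L1/L2 mixing is
    ``l1_ratio``.
    """
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (X - mean) / sd_safe
    cv = KFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    # l1_ratio=0 is unsupported by the coordinate-descent path; floor it
    l1_ratio = max(config.alpha, 1e-3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        enet = ElasticNetCV(
            l1_ratio=l1_ratio,
            alphas=config.n_lambdas,  # number of points on the penalty path
            cv=cv,
            max_iter=5000,
        )
        enet.fit(Xs, y)
        lam = float(enet.alpha_)
        if config.lambda_rule == "1se":
            mse = enet.mse_path_.mean(axis=1)
            se = enet.mse_path_.std(axis=1, ddof=1) / np.sqrt(enet.mse_path_.shape[1])
            i_min = int(np.argmin(mse))
            thresh = mse[i_min] + se[i_min]
            # alphas_ are descending; pick the largest penalty within 1 SE
            candidates = np.nonzero(mse <= thresh)[0]
            lam = float(enet.alphas_[candidates[0]])
            enet = ElasticNet(alpha=lam, l1_ratio=l1_ratio, max_iter=5000)
            enet.fit(Xs, y)
    coef_std = enet.coef_
    coef_raw = coef_std / sd_safe
    intercept = float(enet.intercept_ - np.sum(coef_raw * mean))
    return coef_raw, intercept, lam


def train_elastic_net(
    beta: BetaMatrix, pace: pd.Series, config: TrainConfig | None = None
) -> TrainResult:
    """Fit the CpG predictor of pace and export nonzero weights.

    The returned model scores raw betas directly (coefficients are
    back-transformed from the standardized fit).  A zero-variance
    criterion yields an intercept-only model.
    """
    config = config or TrainConfig()
    X, y, probe_ids, samples = _aligned_xy(beta, pace, config)
    if len(y) < config.n_folds:
        raise PacemeterError(
            f"n_samples={len(y)} is smaller than n_folds={config.n_folds}"
        )
    if np.std(y) == 0:
        warnings.warn("zero-variance criterion; returning intercept-only model")
        model = WeightModel(float(np.mean(y)), pd.Series(dtype=float), {"name": "intercept-only"})
        return TrainResult(model, float("nan"), float("nan"), 0)

    coef, intercept, lam = _fit_enet(X, y, config)
    nz = np.nonzero(coef)[0]
    weights = pd.Series(coef[nz], index=[probe_ids[i] for i in nz])
    model = WeightModel(
        intercept,
        weights,
        {"name": "pace-enet", "alpha": config.alpha, "lambda": lam, "n_train": len(y)},
    )
    pred = intercept + X @ coef
    r = float(np.corrcoef(pred, y)[0, 1]) if len(nz) else float("nan")
    return TrainResult(model, r, lam, int(len(nz)))


def predict(model: WeightModel, beta: BetaMatrix) -> pd.Series:
    """Convenience raw linear score (no imputation; see scores.score for policies)."""
    sub = beta.values.reindex(model.probe_ids)
    if sub.isna().any().any():
        raise PacemeterError("beta matrix lacks model probes or has missing cells")
    vals = model.intercept + model.weights.to_numpy() @ sub.to_numpy()
    return pd.Series(vals, index=beta.sample_ids, name="score")


def bootstrap_cv(
    beta: BetaMatrix,
    pace: pd.Series,
    reps: int = 100,
    test_fraction: float = 0.10,
    config: TrainConfig | None = None,
) -> BootstrapReport:
    """Repeated random train/test splits (default 90/10 x 100).

    Each repetition trains :func:`train_elastic_net` on the training
    split, records the held-out correlation between predicted and
    measured pace, and scores the full cohort; the mean pairwise
    correlation among the repetition scores quantifies how stable the
    learned algorithm is across resamples.
    """
    config = config or TrainConfig()
    if reps < 1:
        raise PacemeterError("reps must be >= 1")
    X, y, probe_ids, samples = _aligned_xy(beta, pace, config)
    n = len(y)
    n_test = int(round(n * test_fraction))
    if n_test < 3:
        raise PacemeterError(f"test split of {n_test} samples is too small (<3)")
    rng = np.random.default_rng(config.seed)
    oos_r = np.empty(reps)
    ins_r = np.empty(reps)
    n_sel = np.empty(reps, dtype=int)
    cohort_scores = np.empty((reps, n))
    for rep in range(reps):
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        rep_cfg = TrainConfig(
            alpha=config.alpha,
            lambda_rule=config.lambda_rule,
            n_folds=config.n_folds,
            n_lambdas=config.n_lambdas,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        coef, intercept, _ = _fit_enet(X[train_idx], y[train_idx], rep_cfg)
        pred_train = intercept + X[train_idx] @ coef
        pred_test = intercept + X[test_idx] @ coef
        cohort_scores[rep] = intercept + X @ coef
        n_sel[rep] = int(np.count_nonzero(coef))
        ins_r[rep] = _safe_corr(pred_train, y[train_idx])
        oos_r[rep] = _safe_corr(pred_test, y[test_idx])
    pair_r = _mean_pairwise_corr(cohort_scores)
    return BootstrapReport(
        oos_r=oos_r,
        in_sample_r=ins_r,
        n_selected=n_sel,
        score_pairwise_r=pair_r,
        test_fraction=test_fraction,
    )


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _mean_pairwise_corr(scores: np.ndarray) -> float:
    ok = scores[np.std(scores, axis=1) > 0]
    if len(ok) < 2:
        return float("nan")
    cm = np.corrcoef(ok)
    iu = np.triu_indices_from(cm, k=1)
    return float(np.mean(cm[iu]))
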