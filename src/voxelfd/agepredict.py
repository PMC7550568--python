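"""Feature-age association and individual age prediction.

Two evaluation tools for a morphometric feature (FD, mean cortical
thickness, gyrification index, ...):

* Pearson correlation between the feature and age, with the usual
  two-sided t-distribution p-value.
* Age prediction by ordinary least squares on (feature, eTIV, sex) in a
  repeated 5-fold cross-validation loop.  Within each fold every feature
  is standardized using the *training* fold's mean and standard deviation
  only, so no information leaks from the test set.  Performance is the
  mean absolute error (MAE, years) pooled over all test predictions of a
  repetition; the reported score averages the repetitions.  Significance
  comes from a permutation test: ages are randomly permuted, the CV score
  recomputed, and p = (1 + #{null MAE <= observed}) / (1 + n_permutations)
  — the add-one estimator, so p is never exactly zero and the smallest
  attainable value with 5000 permutations is 1/5001.

The inner OLS is solved directly with numpy's least-squares routine; the
model is deliberately plain (no regularization), matching how such small
tabular cohorts are analysed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConstantInputError,
    LengthMismatchError,
    MissingValuesError,
    TooFewSubjectsError,
)


@dataclass(frozen=True)
class CVConfig:
    """Configuration of the repeated-CV age-prediction evaluation."""

    feature_cols: tuple[str, ...] = ("FD", "eTIV", "sex")
    target: str = "age"
    n_folds: int = 5
    n_repetitions: int = 1000
    n_permutations: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if min(self.n_repetitions, self.n_permutations) < 1:
            raise ValueError("repetition/permutation counts must be >= 1")


@dataclass
class CVResult:
    """Repeated-CV outcome, optionally with the permutation null."""

    mae_per_repetition: np.ndarray
    mean_mae: float
    null_maes: np.ndarray | None = None
    p_value: float | None = None


def pearson_assoc(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r between a feature and age with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise LengthMismatchError(f"shapes {x.shape} and {y.shape} differ")
    if len(x) < 3:
        raise TooFewSubjectsError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _design(cohort: pd.DataFrame, config: CVConfig) -> tuple[np.ndarray, np.ndarray]:
    cols = list(config.feature_cols) + [config.target]
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise MissingValuesError(f"columns missing from cohort: {missing}")
    sub = cohort[cols]
    if sub.isna().any().any():
        raise MissingValuesError("missing values in model columns")
    X = sub[list(config.feature_cols)].to_numpy(dtype=float)
    y = sub[config.target].to_numpy(dtype=float)
    if len(y) < 2 * config.n_folds:
        raise TooFewSubjectsError(
            f"need >= {2 * config.n_folds} subjects for {config.n_folds}-fold CV"
        )
    return X, y


def _cv_mae(X: np.ndarray, y: np.ndarray, n_folds: int,
            rng: np.random.Generator) -> float:
    """One shuffled k-fold CV; MAE pooled over all test predictions.

    Folds are a uniform random shuffle cut into contiguous blocks; any
    remainder subjects are spread one per fold.  Standardization uses the
    training fold only.
    """
    n = len(y)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    abs_err = np.empty(n)
    pos = 0
    for test_idx in folds:
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        Xtr, ytr = X[mask], y[mask]
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd[sd == 0] = 1.0  # constant feature carries no information
        A = np.column_stack([np.ones(len(ytr)), (Xtr - mu) / sd])
        coef, *_ = np.linalg.lstsq(A, ytr, rcond=None)
        Ate = np.column_stack([np.ones(len(test_idx)), (X[test_idx] - mu) / sd])
        pred = Ate @ coef
        abs_err[pos:pos + len(test_idx)] = np.abs(pred - y[test_idx])
        pos += len(test_idx)
    return float(abs_err.mean())


def repeated_cv_mae(cohort: pd.DataFrame, config: CVConfig) -> CVResult:
    """Repeated shuffled k-fold CV of the OLS age model.

    Each repetition reshuffles the fold assignment; the result stores the
    per-repetition MAEs and their arithmetic mean.  Fully reproducible
    from ``config.seed``.
    """
    X, y = _design(cohort, config)
    seeds = np.random.SeedSequence([config.seed, 1]).spawn(config.n_repetitions)
    maes = np.array([
        _cv_mae(X, y, config.n_folds, np.random.default_rng(s)) for s in seeds
    ])
    return CVResult(mae_per_repetition=maes, mean_mae=float(maes.mean()))


def permutation_test(cohort: pd.DataFrame, config: CVConfig,
                     observed: CVResult, perm_reps: int = 1) -> CVResult:
    """Permutation significance of an observed repeated-CV MAE.

    For each permutation the ages are shuffled (breaking any feature-age
    link) and the CV MAE recomputed — by default one CV per permutation;
    ``perm_reps`` allows averaging several for sensitivity checks.  Returns
    a copy of ``observed`` with the null distribution and add-one p-value
    attached.
    """
    X, y = _design(cohort, config)
    seeds = np.random.SeedSequence([config.seed, 2]).spawn(config.n_permutations)
    null = np.empty(config.n_permutations)
    for i, s in enumerate(seeds):
        rng = np.random.default_rng(s)
        yperm = rng.permutation(y)
        null[i] = np.mean([_cv_mae(X, yperm, config.n_folds, rng)
                           for _ in range(perm_reps)])
    p = (1.0 + np.sum(null <= observed.mean_mae)) / (1.0 + config.n_permutations)
    return CVResult(mae_per_repetition=observed.mae_per_repetition,
                    mean_mae=observed.mean_mae, null_maes=null,
                    p_value=float(p))


def evaluate_feature(cohort: pd.DataFrame, config: CVConfig,
                     with_permutation: bool = True) -> CVResult:
    """Convenience wrapper: repeated CV followed by the permutation test."""
    result = repeated_cv_mae(cohort, config)
    if with_permutation:
        result = permutation_test(cohort, config, result)
    return result
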