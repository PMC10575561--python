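"""Per-participant skipping (logistic) and gaze-duration (OLS) models,
scored by 10-fold cross-validated variation explained.

Models are plain maximum-likelihood fits with an intercept and no
regularization. Scores pool held-out losses over folds — R-squared for
durations, McFadden pseudo-R-squared for skipping — against fold-specific
intercept-only null models; both metrics can be negative under
cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.model_selection import KFold
import warnings

LOGISTIC_TOL = 1e-8
LOGISTIC_MAX_ITER = 500


@dataclass(frozen=True)
class ModelSpec:
    outcome: str
    predictor_groups: dict[str, tuple[str, ...]] = field(default_factory=dict)
    link: str = "identity"  # "identity" | "logistic"

    @property
    def predictors(self) -> list[str]:
        cols: list[str] = []
        for group in self.predictor_groups.values():
            for c in group:
                if c in cols:
                    raise ValueError(f"predictor {c!r} appears in more than one group")
                cols.append(c)
        if not cols:
            raise ValueError("at least one predictor required")
        return cols


@dataclass(frozen=True)
class ScoreResult:
    participant: object
    model_label: str
    score: float
    metric: str
    n_rows: int


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> LogisticRegression:
    if y.min() == y.max():
        raise ValueError("degenerate outcome: all training rows share one class")
    # C=inf: plain maximum likelihood, no regularization
    model = LogisticRegression(
        C=np.inf, tol=LOGISTIC_TOL, max_iter=LOGISTIC_MAX_ITER, solver="lbfgs"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model.fit(X, y)
        except ConvergenceWarning:
            raise RuntimeError(
                f"logistic fit failed to converge in {LOGISTIC_MAX_ITER} iterations "
                f"(n={len(y)}, event rate={y.mean():.4f}); possible separation"
            ) from None
    return model


def fit_predict_cv(
    table: pd.DataFrame,
    columns: list[str],
    outcome: str,
    link: str,
    k_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Held-out predictions for one participant's rows under k-fold CV.

    Folds are assigned by row with a fixed seed, so calls with the same
    table, seed and fold count (but different predictors) share assignments.
    Returns a frame aligned to ``table`` with columns ``y``, ``prediction``
    (probability for the logistic link) and ``null_prediction`` (the training
    fold's intercept-only prediction).
    """
    n = len(table)
    if n < k_folds:
        raise ValueError(f"{n} rows is fewer than {k_folds} folds")
    X = table[columns].to_numpy(dtype=float)
    y = table[outcome].to_numpy(dtype=float)
    pred = np.full(n, np.nan)
    null_pred = np.full(n, np.nan)
    fold_id = np.full(n, -1)
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for fold, (train, test) in enumerate(kf.split(X)):
        if link == "logistic":
            model = _fit_logistic(X[train], y[train].astype(int))
            pred[test] = model.predict_proba(X[test])[:, 1]
            null_pred[test] = y[train].mean()
        elif link == "identity":
            model = LinearRegression().fit(X[train], y[train])
            pred[test] = model.predict(X[test])
            null_pred[test] = y[train].mean()
        else:
            raise ValueError(f"unknown link {link!r}")
        fold_id[test] = fold
    return pd.DataFrame(
        {"y": y, "prediction": pred, "null_prediction": null_pred, "fold": fold_id},
        index=table.index,
    )


def score_r2(outcomes: np.ndarray, predictions: np.ndarray, null_predictions: np.ndarray) -> float:
    """Cross-validated R-squared: 1 - SS_res / SS_tot with both sums pooled
    over folds and SS_tot taken against each fold's training mean."""
    y = np.asarray(outcomes, dtype=float)
    ss_res = float(np.sum((y - predictions) ** 2))
    ss_tot = float(np.sum((y - null_predictions) ** 2))
    if ss_tot == 0:
        raise ValueError("zero total sum of squares")
    return 1.0 - ss_res / ss_tot


def _bernoulli_nll(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def score_mcfadden(outcomes: np.ndarray, probabilities: np.ndarray, null_rates: np.ndarray) -> float:
    """Cross-validated McFadden R-squared: 1 - L_model / L_null with pooled
    held-out negative log-likelihoods."""
    y = np.asarray(outcomes, dtype=float)
    null_rates = np.asarray(null_rates, dtype=float)
    if np.any((null_rates <= 0) | (null_rates >= 1)):
        raise ValueError("a training fold had an all-one or all-zero outcome")
    l_model = _bernoulli_nll(y, np.asarray(probabilities, dtype=float))
    l_null = _bernoulli_nll(y, null_rates)
    return 1.0 - l_model / l_null


def cv_score(
    table: pd.DataFrame,
    columns: list[str],
    outcome: str,
    link: str,
    k_folds: int = 10,
    seed: int = 0,
) -> float:
    """Cross-validated score (R-squared or McFadden) for one predictor set."""
    res = fit_predict_cv(table, columns, outcome, link, k_folds=k_folds, seed=seed)
    if link == "logistic":
        return score_mcfadden(res["y"], res["prediction"], res["null_prediction"])
    return score_r2(res["y"], res["prediction"], res["null_prediction"])


def fit_coefficients(
    table: pd.DataFrame, columns: list[str], outcome: str, link: str
) -> pd.Series:
    """Full-data maximum-likelihood coefficients (no CV), named by predictor."""
    X = table[columns].to_numpy(dtype=float)
    y = table[outcome].to_numpy(dtype=float)
    if link == "logistic":
        model = _fit_logistic(X, y.astype(int))
        coefs = model.coef_.ravel()
    else:
        model = LinearRegression().fit(X, y)
        coefs = model.coef_
    return pd.Series(coefs, index=columns)


def fit_skipped_refixation_model(
    skipped_table: pd.DataFrame,
    entropy_col: str = "parafoveal_entropy_bits",
    outcome_col: str = "later_regressive_fixation",
) -> float:
    """Logistic coefficient of later regressive fixation of first-pass-skipped
    words on their pre-skip parafoveal entropy (standardized).

    Positive means less identifiable skipped words are more often returned to.
    """
    if skipped_table.empty:
        raise ValueError("no first-pass-skipped tokens")
    x = skipped_table[entropy_col].to_numpy(dtype=float)
    y = skipped_table[outcome_col].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("degenerate outcome: every skipped word has the same refixation status")
    z = (x - x.mean()) / x.std()
    model = _fit_logistic(z[:, None], y.astype(int))
    return float(model.coef_[0, 0])
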