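"""Ensemble purchase classification with nested cross-validation.

Whether a customer buys (purchase amount > 0) is predicted from the
associate's Peak Immersion, the customer's dwell time, and the loyal /
companion flags.  Three heterogeneous tree learners — a random forest and
two independent gradient-boosting implementations — are tuned separately
by an inner grid search, and their predicted probabilities are averaged
with equal weights.  Performance is reported from a stratified outer
5-fold cross-validation: sensitivity, specificity, accuracy, AUC and the
Brier-style MSE on probabilities, pooled over the outer test folds (as
confusion-count aggregates, not fold means).  A logistic-regression
baseline is always evaluated alongside the ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier
from lightgbm import LGBMClassifier

DEFAULT_FEATURES = ("peak_immersion", "dwell_min", "loyal", "companion")

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {"n_estimators": [100], "max_depth": [4, None]},
    "gradient_boosting_a": {"n_estimators": [100], "max_depth": [3], "learning_rate": [0.1, 0.3]},
    "gradient_boosting_b": {"n_estimators": [100], "num_leaves": [15, 31], "learning_rate": [0.1]},
}


@dataclass(frozen=True)
class PredictionSpec:
    features: tuple[str, ...] = DEFAULT_FEATURES
    label: str = "purchased"
    hyperparameter_grid: Mapping[str, Mapping[str, list]] = field(
        default_factory=lambda: DEFAULT_GRIDS
    )
    n_folds: int = 5
    inner_folds: int = 3
    decision_threshold: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must be in (0, 1)")


def discretize_purchase(table: pd.DataFrame, amount_col: str = "purchase_usd") -> pd.DataFrame:
    """Add the binary ``purchased`` label: amount strictly greater than zero."""
    amounts = table[amount_col].to_numpy(float)
    if np.any(amounts < 0):
        raise ValueError("negative purchase amount")
    out = table.copy()
    out["purchased"] = (amounts > 0).astype(int)
    return out


def classification_metrics(
    labels: Sequence[int], probabilities: Sequence[float], threshold: float = 0.5
) -> dict[str, float]:
    """Sensitivity, specificity, accuracy, rank AUC, and Brier MSE."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if len(y) != len(p):
        raise ValueError("labels and probabilities must have equal length")
    if not set(np.unique(y)).issubset({0, 1}):
        raise ValueError("labels must be binary")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined for one-class labels")
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return {
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "accuracy": (tp + tn) / len(y),
        "auc": float(roc_auc_score(y, p)),
        "mse": float(np.mean((p - y) ** 2)),
    }


def _make_learner(name: str, params: Mapping, seed: int):
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if name == "gradient_boosting_a":
        return XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss", verbosity=0, **params
        )
    if name == "gradient_boosting_b":
        return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1, **params)
    raise ValueError(f"unknown learner: {name!r}")


@dataclass
class PredictionReport:
    per_fold: list[dict]
    pooled: dict[str, float]
    baseline_pooled: dict[str, float]
    selected_hyperparameters: dict[str, list[dict]]
    n: int
    spec: PredictionSpec

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pooled": self.pooled,
            "baseline_pooled": self.baseline_pooled,
            "per_fold": self.per_fold,
            "selected_hyperparameters": self.selected_hyperparameters,
            "features": list(self.spec.features),
            "n_folds": self.spec.n_folds,
            "decision_threshold": self.spec.decision_threshold,
            "rng_seed": self.spec.rng_seed,
        }


def tune_and_evaluate(table: pd.DataFrame, spec: PredictionSpec) -> PredictionReport:
    """Nested cross-validated ensemble evaluation.

    Outer loop: stratified ``n_folds``-fold split.  Inner loop, per
    learner: exhaustive grid search over the learner's candidate
    hyperparameters selecting by inner-CV accuracy on the outer training
    fold.  The ensemble probability on the outer test fold is the
    unweighted mean of the three tuned learners' probabilities.  Pooled
    metrics aggregate predictions across all outer test folds.
    """
    if spec.label not in table.columns:
        raise ValueError(f"label column {spec.label!r} missing; run discretize_purchase first")
    X = table[list(spec.features)].astype(float).reset_index(drop=True)
    y = table[spec.label].to_numpy(int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if len(y) < 10 * spec.n_folds:
        raise ValueError("need at least 10 rows per fold")

    outer = StratifiedKFold(n_splits=spec.n_folds, shuffle=True, random_state=spec.rng_seed)
    per_fold = []
    selected: dict[str, list[dict]] = {name: [] for name in spec.hyperparameter_grid}
    all_probs = np.empty(len(y))
    all_base = np.empty(len(y))

    for fold, (tr, te) in enumerate(outer.split(X, y)):
        probs = []
        for name, grid in spec.hyperparameter_grid.items():
            search = GridSearchCV(
                _make_learner(name, {}, spec.rng_seed),
                dict(grid),
                scoring="accuracy",
                cv=StratifiedKFold(spec.inner_folds, shuffle=True, random_state=spec.rng_seed),
                n_jobs=1,
            )
            search.fit(X.iloc[tr], y[tr])
            selected[name].append(search.best_params_)
            probs.append(search.best_estimator_.predict_proba(X.iloc[te])[:, 1])
        ens = np.mean(probs, axis=0)
        all_probs[te] = ens
        base = Pipeline(
            [("scale", StandardScaler()), ("lr", LogisticRegression(max_iter=2000))]
        ).fit(X.iloc[tr], y[tr])
        all_base[te] = base.predict_proba(X.iloc[te])[:, 1]
        fold_metrics = classification_metrics(y[te], ens, spec.decision_threshold)
        fold_metrics["fold"] = fold
        per_fold.append(fold_metrics)

    pooled = classification_metrics(y, all_probs, spec.decision_threshold)
    baseline = classification_metrics(y, all_base, spec.decision_threshold)
    return PredictionReport(
        per_fold=per_fold,
        pooled=pooled,
        baseline_pooled=baseline,
        selected_hyperparameters=selected,
        n=len(y),
        spec=spec,
    )


def holdout_evaluate(
    table: pd.DataFrame, spec: PredictionSpec, train_fraction: float = 0.5
) -> dict[str, float]:
    """50/50 holdout variant: tune on one half, report pooled metrics on the other."""
    X = table[list(spec.features)].astype(float).reset_index(drop=True)
    y = table[spec.label].to_numpy(int)
    rng = np.random.default_rng(spec.rng_seed)
    idx = rng.permutation(len(y))
    n_train = int(round(train_fraction * len(y)))
    tr, te = idx[:n_train], idx[n_train:]
    probs = []
    for name, grid in spec.hyperparameter_grid.items():
        search = GridSearchCV(
            _make_learner(name, {}, spec.rng_seed),
            dict(grid),
            scoring="accuracy",
            cv=StratifiedKFold(spec.inner_folds, shuffle=True, random_state=spec.rng_seed),
            n_jobs=1,
        )
        search.fit(X.iloc[tr], y[tr])
        probs.append(search.best_estimator_.predict_proba(X.iloc[te])[:, 1])
    return classification_metrics(y[te], np.mean(probs, axis=0), spec.decision_threshold)
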