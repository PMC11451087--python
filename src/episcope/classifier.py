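"""Random-forest outcome classification with LOOCV and temporal transfer.

The classifier is trained on the t0 beta values of the LASSO-selected
probes and evaluated three ways, mirroring the study design:

* **LOOCV** on t0 — each fold holds out a single patient, so the per-fold
  accuracy/precision/recall/F1 are 0/1 indicators. Summaries are reported
  as mean ± population SD of those indicators; for a 0/1 indicator with
  mean m the SD is exactly sqrt(m(1-m)). Precision/recall/F1 use the
  undefined-as-zero convention for folds where they are undefined (a held
  out true negative contributes 0 to recall, etc.).
* **self-test** on the training data (deep trees reach 1.0 throughout — a
  reported baseline, not a performance claim).
* **temporal transfer** — the t0-trained forest predicts the same
  patients' t2 samples; pooled confusion-matrix metrics and the per-sample
  vote fractions are reported.

The positive class is ``non_survivor`` (coded 1); the decision threshold
on the vote fraction is 0.5. The EpiSAVE variant appends the min-max
scaled SAVE clinical score as one extra feature column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .io import CohortTable

__all__ = [
    "ForestConfig",
    "ClassifierReport",
    "train_forest",
    "predict_vote_fraction",
    "loocv_evaluate",
    "self_test",
    "transfer_test",
    "pooled_metrics",
    "episave_augment",
]

POSITIVE_CLASS = "non_survivor"  # coded 1 everywhere


@dataclass
class ForestConfig:
    n_trees: int = 500
    max_features: str | float = "sqrt"
    min_leaf: int = 1
    bootstrap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class ClassifierReport:
    """LOOCV indicators, self-test and transfer-test metrics for one model."""

    loocv_indicators: pd.DataFrame | None = None  # per-patient 0/1 indicators
    loocv_summary: pd.DataFrame | None = None  # metric -> mean, sd
    train_self_metrics: dict | None = None
    test_metrics: dict | None = None
    test_probabilities: pd.Series | None = None  # vote fraction, positive class
    positive_class: str = POSITIVE_CLASS
    feature_ids: list[str] = field(default_factory=list)
    config: ForestConfig | None = None


def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
    counts = np.bincount(y, minlength=2)
    if counts[0] < 2 or counts[1] < 2:
        raise ValueError(f"need >= 2 samples per class, have {counts.tolist()}")
    return X, y


def train_forest(X, y, config: ForestConfig | None = None) -> RandomForestClassifier:
    """Fit a Gini-criterion random forest; deterministic given ``config.seed``."""
    config = config or ForestConfig()
    X, y = _check_xy(X, y)
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion="gini",
        max_features=config.max_features,
        min_samples_leaf=config.min_leaf,
        bootstrap=config.bootstrap,
        random_state=config.seed,
    )
    forest.fit(X, y)
    return forest


def predict_vote_fraction(forest: RandomForestClassifier, X) -> np.ndarray:
    """Fraction of trees voting for the positive class, in [0, 1]."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != forest.n_features_in_:
        raise ValueError(
            f"feature mismatch: forest expects {forest.n_features_in_} features, got {X.shape[1]}"
        )
    proba = forest.predict_proba(X)
    pos_col = int(np.where(forest.classes_ == 1)[0][0])
    return proba[:, pos_col]


def pooled_metrics(y_true, y_pred) -> dict:
    """Confusion-matrix metrics with positive class = 1 (non_survivor)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    n = tp + fp + tn + fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "accuracy": (tp + tn) / n,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
    }


def fold_indicators(truth: int, pred: int) -> dict:
    """Single-sample 0/1 metrics for one LOOCV fold (undefined-as-zero)."""
    correct = int(truth == pred)
    return {
        "accuracy": correct,
        "precision": int(pred == 1 and truth == 1),
        "recall": int(truth == 1 and pred == 1),
        "f1": int(truth == 1 and pred == 1),
    }


def summarize_indicators(ind: pd.DataFrame) -> pd.DataFrame:
    """Mean ± population SD per metric (SD of 0/1 indicators = sqrt(m(1-m)))."""
    means = ind.mean(axis=0)
    sds = ind.std(axis=0, ddof=0)
    return pd.DataFrame({"mean": means, "sd": sds})


def loocv_evaluate(X, y, config: ForestConfig | None = None, sample_ids=None) -> ClassifierReport:
    """Leave-one-out cross-validation of the forest on the training matrix."""
    config = config or ForestConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"LOOCV needs n >= 3, have {n}")
    ids = list(sample_ids) if sample_ids is not None else list(range(n))
    rows = []
    for i in range(n):
        mask = np.arange(n) != i
        forest = train_forest(X[mask], y[mask], config)
        vote = predict_vote_fraction(forest, X[i : i + 1])[0]
        pred = int(vote >= 0.5)
        rows.append({"patient_id": ids[i], "truth": int(y[i]), "pred": pred, "vote": vote}
                    | fold_indicators(int(y[i]), pred))
    ind = pd.DataFrame(rows).set_index("patient_id")
    summary = summarize_indicators(ind[["accuracy", "precision", "recall", "f1"]])
    return ClassifierReport(loocv_indicators=ind, loocv_summary=summary, config=config)


def self_test(forest: RandomForestClassifier, X, y) -> dict:
    votes = predict_vote_fraction(forest, X)
    return pooled_metrics(y, (votes >= 0.5).astype(int))


def transfer_test(forest: RandomForestClassifier, X_test, y, sample_ids=None) -> ClassifierReport:
    """Evaluate a t0-trained forest on the t2 matrix (features aligned)."""
    votes = predict_vote_fraction(forest, X_test)
    preds = (votes >= 0.5).astype(int)
    metrics = pooled_metrics(y, preds)
    ids = list(sample_ids) if sample_ids is not None else list(range(len(votes)))
    return ClassifierReport(
        test_metrics=metrics,
        test_probabilities=pd.Series(votes, index=ids, name="vote_fraction"),
    )


def episave_augment(X, cohort: CohortTable, patient_ids) -> np.ndarray:
    """Append the min-max scaled SAVE score as one extra feature column.

    Scaling to [0, 1] puts the score on the beta-value range; a constant
    score maps to 0.5 (an uninformative column). Missing scores raise.
    """
    X = np.asarray(X, dtype=float)
    save = cohort.data.loc[list(patient_ids), "save_score"].to_numpy(dtype=float)
    if np.isnan(save).any():
        missing = [p for p, s in zip(patient_ids, save) if np.isnan(s)]
        raise ValueError(f"missing SAVE score for patients {missing[:5]}")
    lo, hi = save.min(), save.max()
    scaled = np.full_like(save, 0.5) if hi == lo else (save - lo) / (hi - lo)
    return np.column_stack([X, scaled])
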