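"""Cross-validated logistic-regression experiments.

Two experiments mirror the clinical questions:

1. **EZ-channel prediction** — can per-channel features (averaged leading
   eigenvector component, and/or source-sink metrics) distinguish
   clinically annotated EZ channels from the rest? Evaluated with
   leave-one-patient-out cross-validation: every fold holds out all
   channels of one patient.
2. **Surgical-outcome prediction** — do the per-patient EZ-minus-nonEZ
   feature differences (theta and its source-sink analogues) separate
   Engel 1 (seizure-free, success) from Engel 2-4 (failure)? Evaluated
   with stratified k-fold cross-validation at the patient level.

Both use unpenalized maximum-likelihood logistic regression and pick the
decision threshold on the training fold's ROC curve by maximizing
Youden's J = sensitivity + specificity - 1; the threshold is then applied
to the held-out fold. Accuracy, sensitivity and specificity are reported
per fold and as means, in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "PatientRecord",
    "CVResult",
    "FEATURE_SETS",
    "fit_logistic",
    "optimal_threshold",
    "predict_ez_loocv",
    "predict_outcome_cv",
    "compute_metrics",
]

# Feature-column sets for the three models: the eigenvector biomarker alone,
# the source-sink metrics alone, and their combination.
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "evc": ("evc_avg",),
    "ssm": ("sink_index_avg", "source_influence_avg", "sink_connectivity_avg"),
    "combined": (
        "evc_avg",
        "sink_index_avg",
        "source_influence_avg",
        "sink_connectivity_avg",
    ),
}


@dataclass
class PatientRecord:
    """One patient's channel features, EZ annotation, and surgical outcome.

    ``features`` rows align with ``ez_mask``; ``outcome`` is the Engel
    class (1 = seizure-free; 2-4 = persistent seizures).
    """

    patient_id: str
    features: pd.DataFrame
    ez_mask: np.ndarray
    outcome: int = 1

    def __post_init__(self) -> None:
        self.ez_mask = np.asarray(self.ez_mask, dtype=bool)
        if len(self.features) != len(self.ez_mask):
            raise ValueError(
                f"patient {self.patient_id}: {len(self.features)} feature rows "
                f"vs mask length {len(self.ez_mask)}"
            )
        if self.outcome not in (1, 2, 3, 4):
            raise ValueError(f"Engel class must be 1-4, got {self.outcome}")

    @property
    def outcome_binary(self) -> int:
        """1 for surgical success (Engel 1), 0 for failure (Engel 2-4)."""
        return int(self.outcome == 1)

    def contrast_features(self, columns: tuple[str, ...]) -> np.ndarray:
        """EZ-minus-nonEZ mean difference of each feature column."""
        ez = self.features.loc[self.ez_mask, list(columns)].mean(axis=0)
        nez = self.features.loc[~self.ez_mask, list(columns)].mean(axis=0)
        return (ez - nez).to_numpy(dtype=float)


@dataclass
class CVResult:
    """Per-fold and mean classification metrics (percent)."""

    per_fold: list[dict] = field(default_factory=list)
    train_auc: list[float] = field(default_factory=list)

    def _mean(self, key: str) -> float:
        vals = [f[key] for f in self.per_fold if np.isfinite(f[key])]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def mean_accuracy(self) -> float:
        return self._mean("accuracy")

    @property
    def mean_sensitivity(self) -> float:
        return self._mean("sensitivity")

    @property
    def mean_specificity(self) -> float:
        return self._mean("specificity")

    def summary_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_fold)
        df["train_auc"] = self.train_auc
        return df

    def to_dict(self) -> dict:
        return {
            "per_fold": self.per_fold,
            "train_auc": self.train_auc,
            "mean_accuracy": self.mean_accuracy,
            "mean_sensitivity": self.mean_sensitivity,
            "mean_specificity": self.mean_specificity,
        }


def fit_logistic(X: np.ndarray, y: np.ndarray, penalty: float = 0.0) -> LogisticRegression:
    """Unpenalized maximum-likelihood logistic fit (optionally ridge).

    ``penalty`` > 0 switches on an L2 penalty of that strength; the
    default is plain maximum likelihood.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(f"need both classes to fit, got only {classes}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    C = 1.0 / penalty if penalty > 0 else np.inf
    model = LogisticRegression(C=C, max_iter=5000)
    model.fit(X, y)
    return model


def optimal_threshold(scores: np.ndarray, y: np.ndarray) -> float:
    """ROC-optimal decision threshold by Youden's J on training scores.

    Maximizes J = sensitivity + specificity - 1 over the ROC operating
    points of the rule ``score >= threshold -> positive``; ties are broken
    toward the smaller threshold. Warns if the scores are uninformative
    (J = 0 everywhere).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required to place a threshold")
    # candidate thresholds: every distinct score (rule is >=, so each score
    # value is a distinct operating point)
    cand = np.unique(scores)
    pos = y == 1
    best_j, best_t = -np.inf, cand[0]
    for t in cand:
        pred = scores >= t
        sens = (pred & pos).sum() / pos.sum()
        spec = (~pred & ~pos).sum() / (~pos).sum()
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    if best_j <= 1e-12:
        warnings.warn(
            "scores are uninformative or inverted; Youden's J <= 0 at every "
            "threshold",
            UserWarning,
            stacklevel=2,
        )
    return float(best_t)


def compute_metrics(pred: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """Accuracy, sensitivity, specificity (percent) from binary vectors.

    A ratio with an empty denominator (no positives, or no negatives, in
    the truth) is reported as NaN with a warning.
    """
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    tp = int((pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    n = pred.size
    acc = 100.0 * (tp + tn) / n
    if tp + fn == 0:
        warnings.warn("no positive cases in truth; sensitivity undefined",
                      UserWarning, stacklevel=2)
        sens = float("nan")
    else:
        sens = 100.0 * tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no negative cases in truth; specificity undefined",
                      UserWarning, stacklevel=2)
        spec = float("nan")
    else:
        spec = 100.0 * tn / (tn + fp)
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec}


def _channel_matrix(
    patients: list[PatientRecord], columns: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([p.features[list(columns)].to_numpy(dtype=float) for p in patients])
    y = np.concatenate([p.ez_mask.astype(int) for p in patients])
    return X, y


def predict_ez_loocv(
    cohort: list[PatientRecord],
    feature_set: str = "evc",
    penalty: float = 0.0,
) -> CVResult:
    """Leave-one-patient-out prediction of EZ vs non-EZ channels.

    Each fold trains on the channels of all other patients, derives the
    ROC-optimal threshold on those training channels, and predicts the
    held-out patient's channels. The held-out patient never influences
    its own fold's model or threshold.
    """
    if len(cohort) < 3:
        raise ValueError("leave-one-patient-out needs at least 3 patients")
    columns = FEATURE_SETS[feature_set]
    result = CVResult()
    for i, test_patient in enumerate(cohort):
        train = cohort[:i] + cohort[i + 1 :]
        X_tr, y_tr = _channel_matrix(train, columns)
        if len(np.unique(y_tr)) < 2:
            raise ValueError(
                f"fold {i} (test patient {test_patient.patient_id}): training "
                "channels contain a single class"
            )
        model = fit_logistic(X_tr, y_tr, penalty=penalty)
        tr_scores = model.predict_proba(X_tr)[:, 1]
        thr = optimal_threshold(tr_scores, y_tr)
        auc = float(roc_auc_score(y_tr, tr_scores))
        X_te = test_patient.features[list(columns)].to_numpy(dtype=float)
        te_scores = model.predict_proba(X_te)[:, 1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            metrics = compute_metrics(te_scores >= thr, test_patient.ez_mask)
        metrics["threshold"] = thr
        metrics["patient_id"] = test_patient.patient_id
        result.per_fold.append(metrics)
        result.train_auc.append(auc)
    return result


def predict_outcome_cv(
    cohort: list[PatientRecord],
    feature_set: str = "evc",
    k: int = 10,
    seed: int = 0,
    penalty: float = 0.0,
) -> CVResult:
    """Stratified k-fold prediction of surgical outcome from theta-style features.

    Each patient contributes one feature vector of EZ-minus-nonEZ mean
    differences (for the eigenvector model this is exactly theta). Folds
    are stratified by binary outcome; per-fold thresholds come from the
    training fold's ROC curve.
    """
    if len(cohort) < k:
        raise ValueError(f"need at least k={k} patients, got {len(cohort)}")
    columns = FEATURE_SETS[feature_set]
    X = np.vstack([p.contrast_features(columns) for p in cohort])
    y = np.array([p.outcome_binary for p in cohort])
    if len(np.unique(y)) < 2:
        raise ValueError("cohort contains a single outcome class")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    result = CVResult()
    for fold, (tr, te) in enumerate(splitter.split(X, y)):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {fold}: training set contains a single class")
        model = fit_logistic(X[tr], y[tr], penalty=penalty)
        tr_scores = model.predict_proba(X[tr])[:, 1]
        thr = optimal_threshold(tr_scores, y[tr])
        auc = float(roc_auc_score(y[tr], tr_scores))
        te_scores = model.predict_proba(X[te])[:, 1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            metrics = compute_metrics(te_scores >= thr, y[te] == 1)
        metrics["threshold"] = thr
        metrics["fold"] = fold
        metrics["test_probabilities"] = te_scores.tolist()
        metrics["test_patients"] = [cohort[j].patient_id for j in te]
        result.per_fold.append(metrics)
        result.train_auc.append(auc)
    return result
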