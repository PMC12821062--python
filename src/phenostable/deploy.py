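"""Deployable cluster assigner: multinomial logistic regression.

Consensus clustering is non-parametric and cannot place an unseen
patient, so the pipeline ends with a supervised multinomial logistic
regression mapping the top-selected variables to the coarse phenogroups.
Missing inputs (the motivating case is CRP, often unavailable at the
point of care) are mean-imputed with the training means before scaling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score
from sklearn.model_selection import StratifiedKFold

from .preprocess import FeatureMatrix


@dataclass
class DeploymentModel:
    coefficients: np.ndarray  # (n_classes, n_features)
    intercepts: np.ndarray  # (n_classes,)
    classes: np.ndarray
    feature_names: list[str]
    imputation_means: np.ndarray  # training means on the raw encoded scale
    scale_center: np.ndarray
    scale_sd: np.ndarray
    cv_f1: float
    cv_f1_ci: tuple[float, float]
    train_accuracy: float
    grid: tuple[float, ...]
    best_c: float
    fold_scores: list[float] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "coefficients": self.coefficients.tolist(),
                "intercepts": self.intercepts.tolist(),
                "classes": self.classes.tolist(),
                "feature_names": self.feature_names,
                "imputation_means": self.imputation_means.tolist(),
                "scale_center": self.scale_center.tolist(),
                "scale_sd": self.scale_sd.tolist(),
                "cv_f1": self.cv_f1,
                "cv_f1_ci": list(self.cv_f1_ci),
                "train_accuracy": self.train_accuracy,
                "grid": list(self.grid),
                "best_c": self.best_c,
                "fold_scores": self.fold_scores,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DeploymentModel":
        d = json.loads(text)
        return cls(
            coefficients=np.asarray(d["coefficients"]),
            intercepts=np.asarray(d["intercepts"]),
            classes=np.asarray(d["classes"]),
            feature_names=list(d["feature_names"]),
            imputation_means=np.asarray(d["imputation_means"]),
            scale_center=np.asarray(d["scale_center"]),
            scale_sd=np.asarray(d["scale_sd"]),
            cv_f1=float(d["cv_f1"]),
            cv_f1_ci=tuple(d["cv_f1_ci"]),
            train_accuracy=float(d["train_accuracy"]),
            grid=tuple(d["grid"]),
            best_c=float(d["best_c"]),
            fold_scores=list(d["fold_scores"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "DeploymentModel":
        return cls.from_json(Path(path).read_text())


def _default_grid() -> tuple[float, ...]:
    return tuple(float(c) for c in np.logspace(-3, 3, 7))


def fit_deployment(
    X: np.ndarray | FeatureMatrix,
    labels: np.ndarray,
    folds: int = 5,
    grid: tuple[float, ...] | None = None,
    seed: int = 0,
) -> DeploymentModel:
    """Grid-searched, cross-validated multinomial logistic regression.

    ``X`` holds the top-selected variables on their raw encoded scale
    (imputation means must live on that scale); standardization happens
    inside the model.  Stratified k-fold CV selects the L2 strength by
    macro-F1; ``cv_f1`` is the mean across folds at the selected setting
    with a 2.5/97.5 percentile interval; the final model is refit on all
    first visits.  Deterministic given the seed.
    """
    feature_names = X.feature_names if isinstance(X, FeatureMatrix) else [
        f"x{j}" for j in range(np.asarray(X).shape[1])
    ]
    X = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    grid = grid or _default_grid()
    min_count = int(counts.min())
    if min_count < folds:
        warnings.warn(
            f"smallest class has {min_count} members; reducing folds to {min_count}",
            stacklevel=2,
        )
        folds = max(2, min_count)

    means = X.mean(axis=0)
    center = means.copy()
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - center) / sd

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    split_idx = list(skf.split(Xs, labels))
    results: dict[float, list[float]] = {}
    for c in grid:
        scores = []
        for tr, te in split_idx:
            clf = LogisticRegression(C=c, max_iter=2000)
            clf.fit(Xs[tr], labels[tr])
            scores.append(f1_score(labels[te], clf.predict(Xs[te]), average="macro"))
        results[c] = scores
    best_c = max(grid, key=lambda c: float(np.mean(results[c])))
    fold_scores = results[best_c]
    cv_f1 = float(np.mean(fold_scores))
    ci = (
        float(np.percentile(fold_scores, 2.5)),
        float(np.percentile(fold_scores, 97.5)),
    )
    final = LogisticRegression(C=best_c, max_iter=2000)
    final.fit(Xs, labels)
    train_acc = float(accuracy_score(labels, final.predict(Xs)))
    return DeploymentModel(
        coefficients=final.coef_,
        intercepts=final.intercept_,
        classes=final.classes_,
        feature_names=feature_names,
        imputation_means=means,
        scale_center=center,
        scale_sd=sd,
        cv_f1=cv_f1,
        cv_f1_ci=ci,
        train_accuracy=train_acc,
        grid=tuple(grid),
        best_c=float(best_c),
        fold_scores=[float(s) for s in fold_scores],
    )


def impute_inputs(x: np.ndarray, model: DeploymentModel) -> np.ndarray:
    """Replace missing entries with the model's training means (raw scale)."""
    x = np.asarray(x, dtype=float)
    out = x.copy()
    nan = np.isnan(out)
    if out.ndim == 1:
        out[nan] = model.imputation_means[nan]
    else:
        for j in range(out.shape[1]):
            out[np.isnan(out[:, j]), j] = model.imputation_means[j]
    return out


def predict_cluster(
    x: np.ndarray, model: DeploymentModel
) -> tuple[np.ndarray, np.ndarray]:
    """Coarse label(s) and class probabilities for (possibly missing) inputs."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != len(model.feature_names):
        raise ValueError("input dimension does not match the model")
    x = impute_inputs(x, model)
    xs = (x - model.scale_center) / model.scale_sd
    z = xs @ model.coefficients.T + model.intercepts
    if z.shape[1] == 1:  # sklearn binary convention
        z = np.column_stack([-z[:, 0], z[:, 0]])
    z = z - z.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    return model.classes[p.argmax(axis=1)], p


def normalized_weights(model: DeploymentModel) -> dict[object, np.ndarray]:
    """Per-class signed weights rescaled so absolute values sum to 100."""
    out = {}
    coefs = model.coefficients
    if coefs.shape[0] == 1:
        coefs = np.vstack([-coefs[0], coefs[0]])
    for cls, w in zip(model.classes, coefs):
        total = np.abs(w).sum()
        if total == 0:
            raise ValueError(f"class {cls} has all-zero weights")
        out[cls] = 100.0 * w / total
    return out


def confusion_and_scores(
    true_labels: np.ndarray, predicted: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Confusion matrix (rows = consensus clusters, columns = predicted),
    accuracy and macro-F1."""
    labels = np.unique(np.concatenate([np.asarray(true_labels), np.asarray(predicted)]))
    cm = confusion_matrix(true_labels, predicted, labels=labels)
    acc = float(accuracy_score(true_labels, predicted))
    f1 = float(f1_score(true_labels, predicted, average="macro"))
    return cm, acc, f1
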