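"""Multinomial logistic regression of density class on texture features.

The model is a standard softmax regression: with class ``a`` as the
reference, each remaining class ``k`` gets a linear score
``eta_k = b_k + w_k . x`` on standardized features, and
``P(class = k | x) = exp(eta_k) / sum_l exp(eta_l)`` (``eta_ref = 0``).
Coefficients maximise the multinomial log-likelihood with a small L2
ridge for numerical stability on separable data.  Evaluation follows the
usual split protocol: a per-class stratified 70/30 train/test partition,
a K x K confusion matrix on the test set, and per-class recall plus
overall accuracy in percent.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax as _softmax

from .phantom import DENSITY_CLASSES

__all__ = [
    "MultinomialModel",
    "ConfusionMatrix",
    "ClassificationMetrics",
    "split_stratified",
    "fit_multinomial_lr",
    "predict_proba",
    "predict",
    "confusion_matrix",
    "classification_metrics",
]


@dataclass
class MultinomialModel:
    """Fitted softmax-regression model with its preprocessing metadata."""

    classes: tuple[str, ...]
    reference: str
    feature_names: list[str]
    coef: np.ndarray  # (K-1, n_features + 1); column 0 is the intercept
    mu: np.ndarray  # per-feature training means
    sigma: np.ndarray  # per-feature training sds
    ridge: float
    converged: bool
    final_grad_norm: float
    dropped_features: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "classes": list(self.classes),
            "reference": self.reference,
            "feature_names": self.feature_names,
            "coef": self.coef.tolist(),
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "ridge": self.ridge,
            "converged": self.converged,
            "final_grad_norm": self.final_grad_norm,
            "dropped_features": self.dropped_features,
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "MultinomialModel":
        d = json.loads(Path(path).read_text())
        return cls(
            classes=tuple(d["classes"]),
            reference=d["reference"],
            feature_names=d["feature_names"],
            coef=np.asarray(d["coef"], dtype=float),
            mu=np.asarray(d["mu"], dtype=float),
            sigma=np.asarray(d["sigma"], dtype=float),
            ridge=d["ridge"],
            converged=d["converged"],
            final_grad_norm=d["final_grad_norm"],
            dropped_features=d.get("dropped_features", []),
        )


@dataclass
class ConfusionMatrix:
    """K x K counts; rows = true class, columns = predicted class."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] != len(self.labels):
            raise ValueError("counts must be K x K matching the labels")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = c.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


@dataclass
class ClassificationMetrics:
    recall_percent: dict[str, float]  # raw, by class (nan if class absent)
    recall_percent_rounded: dict[str, float]  # one decimal, for reporting
    overall_percent: float
    overall_percent_rounded: float


def split_stratified(
    table: pd.DataFrame, train_frac: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class stratified split; the rounding remainder goes to train.

    Each class contributes ``ceil(train_frac * n_class)`` rows to the
    training set.  Reproducible for a fixed seed.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    counts = table["density"].value_counts()
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 rows to split")
    rng = np.random.default_rng(seed)
    train_idx: list = []
    test_idx: list = []
    for cls in sorted(counts.index):
        idx = table.index[table["density"] == cls].to_numpy()
        perm = rng.permutation(len(idx))
        n_train = math.ceil(train_frac * len(idx))
        train_idx.extend(idx[perm[:n_train]])
        test_idx.extend(idx[perm[n_train:]])
    return table.loc[train_idx], table.loc[test_idx]


def _design(x: np.ndarray) -> np.ndarray:
    return np.hstack([np.ones((x.shape[0], 1)), x])


def _nll_grad(w_flat: np.ndarray, xd: np.ndarray, y_onehot: np.ndarray, ridge: float):
    n, p1 = xd.shape
    km1 = y_onehot.shape[1] - 1
    w = w_flat.reshape(km1, p1)
    scores = np.hstack([np.zeros((n, 1)), xd @ w.T])  # reference class score 0
    logp = scores - logsumexp(scores, axis=1, keepdims=True)
    probs = np.exp(logp)
    nll = -float(np.sum(y_onehot * logp))
    pen = w.copy()
    pen[:, 0] = 0.0  # intercepts unpenalised
    nll += 0.5 * ridge * float(np.sum(pen**2))
    resid = probs[:, 1:] - y_onehot[:, 1:]
    grad = resid.T @ xd + ridge * pen
    return nll, grad.ravel()


def fit_multinomial_lr(
    train: pd.DataFrame,
    features: Sequence[str],
    seed: int = 0,
    ridge: float = 1e-4,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> MultinomialModel:
    """Maximum-likelihood softmax regression on standardized features.

    The objective (penalised negative log-likelihood) is strictly convex
    for ``ridge > 0``, so the fit is deterministic regardless of ``seed``
    (kept in the signature for interface symmetry).  Constant features
    are dropped with a warning.  Convergence means the projected-gradient
    norm fell below ``tol`` within ``max_iter`` iterations; otherwise the
    model is returned flagged with its final gradient norm.
    """
    features = list(features)
    classes = tuple(sorted(set(train["density"])))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes in the training data")
    x = train[features].to_numpy(float)
    mu = x.mean(axis=0)
    sigma = x.std(axis=0)
    dropped = [f for f, s in zip(features, sigma) if s == 0]
    if dropped:
        warnings.warn(f"dropping constant features: {dropped}", stacklevel=2)
        keep = [k for k, s in enumerate(sigma) if s > 0]
        features = [features[k] for k in keep]
        x, mu, sigma = x[:, keep], mu[keep], sigma[keep]
    xs = (x - mu) / sigma
    y_codes = np.array([classes.index(c) for c in train["density"]])
    y_onehot = np.eye(len(classes))[y_codes]
    xd = _design(xs)
    km1, p1 = len(classes) - 1, xd.shape[1]
    w0 = np.zeros(km1 * p1)
    res = minimize(
        _nll_grad,
        w0,
        args=(xd, y_onehot, ridge),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-14},
    )
    grad_norm = float(np.linalg.norm(res.jac))
    return MultinomialModel(
        classes=classes,
        reference=classes[0],
        feature_names=features,
        coef=res.x.reshape(km1, p1),
        mu=mu,
        sigma=sigma,
        ridge=ridge,
        converged=bool(grad_norm < 1e-3 or res.success),
        final_grad_norm=grad_norm,
        dropped_features=dropped,
    )


def predict_proba(model: MultinomialModel, rows: pd.DataFrame) -> pd.DataFrame:
    """Per-class probabilities (columns in class order; rows sum to 1)."""
    missing = [f for f in model.feature_names if f not in rows.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    x = rows[model.feature_names].to_numpy(float)
    xs = (x - model.mu) / model.sigma
    scores = np.hstack([np.zeros((xs.shape[0], 1)), _design(xs) @ model.coef.T])
    probs = _softmax(scores, axis=1)
    return pd.DataFrame(probs, index=rows.index, columns=list(model.classes))


def predict(model: MultinomialModel, rows: pd.DataFrame) -> pd.Series:
    """Argmax class; ties resolve to the earlier class in a<b<c<d order."""
    probs = predict_proba(model, rows)
    codes = probs.to_numpy().argmax(axis=1)
    return pd.Series([model.classes[k] for k in codes], index=rows.index, name="predicted")


def confusion_matrix(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    labels: Sequence[str] = DENSITY_CLASSES,
) -> ConfusionMatrix:
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences differ in length")
    labels = tuple(labels)
    index = {c: k for k, c in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"unknown label in pair ({t!r}, {p!r})")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, labels=labels)


def classification_metrics(cm: ConfusionMatrix) -> ClassificationMetrics:
    """Per-class recall and overall accuracy, in percent.

    Recall of class k is ``100 * cm[k, k] / rowsum(k)``; classes with an
    empty row are reported as missing (NaN).  Reported values are rounded
    to one decimal; raw values are kept alongside.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    recall: dict[str, float] = {}
    for k, cls in enumerate(cm.labels):
        row = cm.counts[k].sum()
        recall[cls] = float(100.0 * cm.counts[k, k] / row) if row > 0 else float("nan")
    overall = 100.0 * np.trace(cm.counts) / cm.total
    return ClassificationMetrics(
        recall_percent=recall,
        recall_percent_rounded={c: round(v, 1) for c, v in recall.items()},
        overall_percent=float(overall),
        overall_percent_rounded=round(float(overall), 1),
    )
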