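"""SVM meta-classifier over encoded tool features, cross-validation, and
metric-panel evaluation of any predictor (including upstream tools' raw
calls) with an explicit missing-prediction policy.

The integrator is a soft-margin kernel SVM (RBF by default, C = 1, kernel
width gamma = 1 / n_features) on min-max-scaled features. The decision
threshold is the classifier's sign; no probability calibration.

Upstream tools rarely cover every pair. Two evaluation policies are
provided: ``missing_as_negative`` counts an unpredicted pair as a
non-binding call (a low-coverage tool pays in sensitivity), while
``exclude_missing`` drops unpredicted pairs from all counts (which can
flatter a tool that only answers easy cases). The default is
``missing_as_negative``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .datasets import stratified_kfold
from .metrics import ConfusionCounts, MetricPanel, panel_from_counts

__all__ = [
    "SVMConfig",
    "ScalingParams",
    "TrainedModel",
    "CVResult",
    "scale_features",
    "train",
    "predict",
    "cross_validate",
    "cv_trainer",
    "evaluate_tool_panel",
    "counts_from_calls",
    "MISSING_POLICIES",
]

POSITIVE, NEGATIVE = "positive", "negative"
MISSING_POLICIES = ("missing_as_negative", "exclude_missing")


@dataclass(frozen=True)
class SVMConfig:
    kernel: str = "rbf"
    C: float = 1.0
    gamma: Optional[float] = None  # default 1 / n_features, set at fit time

    def resolved_gamma(self, n_features: int) -> float:
        return self.gamma if self.gamma is not None else 1.0 / n_features


@dataclass
class ScalingParams:
    """Per-feature min-max parameters; constant features map to 0."""

    lo: np.ndarray
    hi: np.ndarray
    names: tuple

    def apply(self, matrix: pd.DataFrame) -> np.ndarray:
        X = matrix[list(self.names)].to_numpy(dtype=float)
        span = self.hi - self.lo
        out = np.zeros_like(X)
        nz = span > 0
        out[:, nz] = (X[:, nz] - self.lo[nz]) / span[nz]
        return np.clip(out, 0.0, 1.0)


@dataclass
class TrainedModel:
    """Fitted classifier + the exact feature subset and scaling it expects."""

    clf: SVC
    scaling: ScalingParams
    feature_names: tuple
    config: SVMConfig
    seed: int

    def save(self, path) -> None:
        joblib.dump(
            {
                "format_version": 1,
                "clf": self.clf,
                "scaling": self.scaling,
                "feature_names": self.feature_names,
                "config": self.config,
                "seed": self.seed,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        d = joblib.load(path)
        return cls(d["clf"], d["scaling"], d["feature_names"], d["config"], d["seed"])


@dataclass
class CVResult:
    fold_counts: list
    fold_panels: list
    pooled_counts: ConfusionCounts
    pooled_panel: MetricPanel


def scale_features(matrix: pd.DataFrame) -> tuple:
    """Min-max scale each feature to [0, 1]; constant features map to 0.

    Returns the scaled array and reusable :class:`ScalingParams` (new data
    is clipped into [0, 1]).
    """
    X = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    params = ScalingParams(
        lo=X.min(axis=0), hi=X.max(axis=0), names=tuple(matrix.columns)
    )
    return params.apply(matrix), params


def _as_binary(labels: Sequence) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "USO":
        return (y == POSITIVE).astype(int)
    return y.astype(int)


def train(
    matrix: pd.DataFrame,
    labels: Sequence,
    config: SVMConfig = SVMConfig(),
    seed: int = 0,
) -> TrainedModel:
    """Fit the SVM integrator on min-max-scaled features."""
    y = _as_binary(labels)
    if np.unique(y).size < 2:
        raise ValueError("training data contains a single class")
    X, scaling = scale_features(matrix)
    clf = SVC(
        kernel=config.kernel,
        C=config.C,
        gamma=config.resolved_gamma(matrix.shape[1]),
        random_state=seed,
    )
    clf.fit(X, y)
    return TrainedModel(clf, scaling, tuple(matrix.columns), config, seed)


def predict(model: TrainedModel, matrix: pd.DataFrame) -> np.ndarray:
    """Binary calls (1 = binding) for each row; deterministic."""
    missing = [c for c in model.feature_names if c not in matrix.columns]
    if missing:
        raise ValueError(f"feature(s) missing from input: {missing}")
    if len(matrix) == 0:
        return np.empty(0, dtype=int)
    X = model.scaling.apply(matrix)
    return model.clf.predict(X).astype(int)


def counts_from_calls(y_true: Sequence, y_pred: Sequence) -> ConfusionCounts:
    t = _as_binary(y_true)
    p = _as_binary(y_pred)
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
    )


def cross_validate(
    matrix: pd.DataFrame,
    labels: Sequence,
    k: int = 10,
    seed: int = 0,
    config: SVMConfig = SVMConfig(),
) -> CVResult:
    """Stratified k-fold CV; out-of-fold predictions pooled into one panel.

    Every record is predicted exactly once; the pooled counts are the sum
    of the per-fold counts, and the headline panel is computed from the
    pooled counts (not averaged across folds).
    """
    y = _as_binary(labels)
    plan = stratified_kfold(y, k=k, seed=seed)
    fold_counts: list = []
    fold_panels: list = []
    for fold in range(k):
        tr, te = plan.train_indices(fold), plan.test_indices(fold)
        model = train(matrix.iloc[tr], y[tr], config=config, seed=seed)
        pred = predict(model, matrix.iloc[te])
        counts = counts_from_calls(y[te], pred)
        fold_counts.append(counts)
        fold_panels.append(panel_from_counts(counts))
    pooled = sum(fold_counts[1:], fold_counts[0])
    return CVResult(fold_counts, fold_panels, pooled, panel_from_counts(pooled))


def cv_trainer(config: SVMConfig = SVMConfig()):
    """Adapter giving :func:`~mirmeta.selection.ifs_select` a CV evaluator."""

    def trainer(matrix: pd.DataFrame, labels, k: int, seed: int) -> MetricPanel:
        return cross_validate(matrix, labels, k=k, seed=seed, config=config).pooled_panel

    return trainer


def evaluate_tool_panel(
    tool_predictions: Mapping,
    truth: Mapping,
    policy: str = "missing_as_negative",
) -> MetricPanel:
    """Metric panel for a (possibly partial) predictor against truth labels.

    ``tool_predictions`` maps (miRNA, target) pairs to "positive"/"negative"
    calls; ``truth`` maps pairs to their true labels. Pairs in truth that
    the tool never scored are handled per ``policy``.
    """
    if not truth:
        raise ValueError("truth mapping is empty")
    if policy not in MISSING_POLICIES:
        raise ValueError(f"policy must be one of {MISSING_POLICIES}")
    extra = set(tool_predictions) - set(truth)
    if extra:
        raise ValueError(f"predictions for pairs absent from truth: {sorted(extra)[:5]}")
    tp = fn = fp = tn = 0
    for pair, true_label in truth.items():
        call = tool_predictions.get(pair)
        if call is None:
            if policy == "exclude_missing":
                continue
            call = NEGATIVE
        if true_label == POSITIVE:
            if call == POSITIVE:
                tp += 1
            else:
                fn += 1
        else:
            if call == POSITIVE:
                fp += 1
            else:
                tn += 1
    return panel_from_counts(ConfusionCounts(tp, fn, fp, tn))
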