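"""Model building: stratified splitting, MCC-scored grid search under
stratified 10-fold cross-validation, and final RF / RBF-SVM fitting.

Scores are deliberately heterogeneous between the two algorithms: a random
forest scores a molecule by the fraction of trees voting "sensitizer"
(in [0, 1], default decision threshold 0.5), whereas the SVM scores by its
uncalibrated signed margin (real line, default threshold 0). ``classify``
labels a molecule a sensitizer iff score > threshold (strict: a tie goes to
the negative class).

Both classifiers use balanced class weights; scaling of continuous features
is refit inside each cross-validation fold on that fold's training portion to
prevent leakage.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import FeatureSet, ScalerParams, SchemaError, apply_scaler, fit_scaler
from .metrics import MetricsBundle

__all__ = [
    "SplitSpec",
    "HyperparameterGrid",
    "DEFAULT_GRID",
    "CVReport",
    "ModelBundle",
    "SplitError",
    "stratified_split",
    "grid_search_cv",
    "fit_model",
    "score",
    "classify",
]

RF = "rf"
SVM = "svm"

DEFAULT_THRESHOLDS = {RF: 0.5, SVM: 0.0}


class SplitError(ValueError):
    """A class has too few members to split or fold."""


@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.2
    seed: int = 43
    stratify_by: str = "label"

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")


def _largest_remainder_allocation(class_counts: dict, test_total: int) -> dict:
    # floor of the proportional share per class, remaining seats by largest
    # fractional remainder (ties: larger class first, then label order)
    n = sum(class_counts.values())
    exact = {c: test_total * k / n for c, k in class_counts.items()}
    alloc = {c: int(math.floor(v)) for c, v in exact.items()}
    remaining = test_total - sum(alloc.values())
    order = sorted(
        class_counts,
        key=lambda c: (-(exact[c] - alloc[c]), -class_counts[c], str(c)),
    )
    for c in order[:remaining]:
        alloc[c] += 1
    return alloc


def stratified_split(records: Sequence, spec: SplitSpec | None = None, labels=None):
    """Split records into (train, test) preserving class proportions.

    Test size is ``ceil(test_fraction * n)``; per-class test counts follow
    largest-remainder proportional allocation, so each class's test share is
    within one compound of the global fraction. Deterministic for fixed seed.
    """
    spec = spec or SplitSpec()
    records = list(records)
    if labels is None:
        labels = [getattr(r, spec.stratify_by) for r in records]
    labels = list(labels)
    if len(labels) != len(records):
        raise ValueError("labels must align with records")

    by_class: dict = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(i)
    for lab, idx in by_class.items():
        if len(idx) < 2:
            raise SplitError(f"class {lab!r} has fewer than 2 members")

    test_total = math.ceil(spec.test_fraction * len(records))
    alloc = _largest_remainder_allocation({c: len(v) for c, v in by_class.items()}, test_total)

    rng = np.random.default_rng(spec.seed)
    test_idx: list[int] = []
    for lab in sorted(by_class, key=str):
        idx = np.array(by_class[lab])
        rng.shuffle(idx)
        test_idx.extend(idx[: alloc[lab]].tolist())
    test_set = set(test_idx)
    train = [records[i] for i in range(len(records)) if i not in test_set]
    test = [records[i] for i in sorted(test_set)]
    return train, test


@dataclass(frozen=True)
class HyperparameterGrid:
    """Search grids for both algorithms; iteration order = listed order."""

    rf_n_estimators: tuple = (10, 50, 100, 250, 500, 1000)
    rf_max_features: tuple = ("sqrt", 0.2, 0.4, 0.6, 0.8, None)
    svm_c: tuple = (0.01, 0.1, 1, 10, 100, 1000)
    svm_gamma: tuple = (1, 0.1, 0.01, 0.001, 0.0001, 0.00001)

    def points(self, algorithm: str) -> list[dict]:
        if algorithm == RF:
            return [
                {"n_estimators": n, "max_features": f}
                for n, f in itertools.product(self.rf_n_estimators, self.rf_max_features)
            ]
        if algorithm == SVM:
            return [
                {"C": c, "gamma": g}
                for c, g in itertools.product(self.svm_c, self.svm_gamma)
            ]
        raise ValueError(f"unknown algorithm {algorithm!r}")


DEFAULT_GRID = HyperparameterGrid()


def _as_matrix_kinds(features):
    if isinstance(features, FeatureSet):
        return features.matrix, list(features.kinds), features
    x = np.asarray(features, dtype=float)
    return x, ["continuous"] * x.shape[1], None


def _encode_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "ifub":
        return labels.astype(int)
    from .curation import SENSITIZER

    return (labels == SENSITIZER).astype(int)


def _make_estimator(algorithm: str, params: dict, seed: int):
    if algorithm == RF:
        return RandomForestClassifier(
            class_weight="balanced", random_state=seed, n_jobs=1, **params
        )
    if algorithm == SVM:
        return SVC(kernel="rbf", class_weight="balanced", random_state=seed, **params)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _raw_score(algorithm: str, estimator, x: np.ndarray) -> np.ndarray:
    if algorithm == RF:
        # fraction of trees voting for the positive class
        votes = np.stack([tree.predict(x) for tree in estimator.estimators_])
        return votes.mean(axis=0)
    return estimator.decision_function(x)


def classify(score_values, threshold: float):
    """1 (sensitizer) iff score is strictly above the threshold."""
    arr = np.asarray(score_values)
    out = (arr > threshold).astype(int)
    return int(out) if arr.ndim == 0 else out


@dataclass
class CVReport:
    algorithm: str
    best_params: dict
    fold_metrics: list[MetricsBundle]
    mean: dict
    sd: dict
    all_results: list  # (params, mean fold MCC) in grid order

    @property
    def mean_mcc(self) -> float:
        return self.mean["MCC"]


def _summarize_folds(folds: list[MetricsBundle]) -> tuple[dict, dict]:
    keys = ("MCC", "ACC", "AUC", "Se", "Sp", "PPV", "NPV", "CCR")
    arr = {k: np.array([f.to_dict()[k] for f in folds], dtype=float) for k in keys}
    mean = {k: float(np.nanmean(v)) for k, v in arr.items()}
    sd = {k: float(np.nanstd(v, ddof=1)) for k, v in arr.items()}
    return mean, sd


def grid_search_cv(
    features,
    labels,
    algorithm: str,
    grid: HyperparameterGrid | None = None,
    folds: int = 10,
    seed: int = 43,
) -> CVReport:
    """Exhaustive grid search scored by mean fold MCC under stratified k-fold
    cross-validation; ties are broken by grid order.

    Continuous features are re-scaled inside every fold on the fold's
    training portion only. Returns the winning point together with its
    per-fold metrics.
    """
    grid = grid or DEFAULT_GRID
    if folds < 2:
        raise ValueError("folds must be >= 2")
    x, kinds, fset = _as_matrix_kinds(features)
    y = _encode_labels(labels)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise SplitError(
            f"minority class has {counts.min()} members; cannot form {folds} stratified folds"
        )

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(x, y))
    for i, (tr, va) in enumerate(splits):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
            raise SplitError(f"fold {i} is degenerate (single class)")

    cont = np.array([k == "continuous" for k in kinds])
    threshold = DEFAULT_THRESHOLDS[algorithm]

    def run_point(params: dict) -> list[MetricsBundle]:
        fold_metrics = []
        for tr, va in splits:
            x_tr, x_va = x[tr].copy(), x[va].copy()
            if cont.any():
                mu = x_tr[:, cont].mean(axis=0)
                sd = x_tr[:, cont].std(axis=0, ddof=0)
                sd[sd == 0.0] = 1.0
                x_tr[:, cont] = (x_tr[:, cont] - mu) / sd
                x_va[:, cont] = (x_va[:, cont] - mu) / sd
            est = _make_estimator(algorithm, params, seed)
            est.fit(x_tr, y[tr])
            s = _raw_score(algorithm, est, x_va)
            pred = classify(s, threshold)
            fold_metrics.append(MetricsBundle.from_predictions(y[va], pred, scores=s))
        return fold_metrics

    best = None
    all_results = []
    for params in grid.points(algorithm):
        fold_metrics = run_point(params)
        mean_mcc = float(np.mean([f.mcc for f in fold_metrics]))
        all_results.append((params, mean_mcc))
        if best is None or mean_mcc > best[1]:  # strict > keeps grid-order ties
            best = (params, mean_mcc, fold_metrics)

    params, _, fold_metrics = best
    mean, sd = _summarize_folds(fold_metrics)
    return CVReport(algorithm, params, fold_metrics, mean, sd, all_results)


@dataclass
class ModelBundle:
    """A fitted classifier plus everything needed to predict and to assess
    reliability: decision threshold, training-fitted scaler, feature schema,
    and the training-set neighbor fingerprints/labels."""

    algorithm: str
    estimator: object
    threshold: float
    scaler: ScalerParams | None
    feature_names: tuple[str, ...]
    feature_kinds: tuple[str, ...] = ()
    reference_fps: np.ndarray | None = None  # training fingerprints (neighbor space)
    reference_labels: np.ndarray | None = None
    seed: int = 43
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.reference_fps is None) != (self.reference_labels is None):
            raise ValueError("reference fingerprints and labels must come together")
        if self.reference_fps is not None and len(self.reference_fps) != len(
            self.reference_labels
        ):
            raise ValueError("reference fingerprints/labels length mismatch")


def fit_model(
    features,
    labels,
    algorithm: str,
    hyperparameters: dict,
    seed: int = 43,
    threshold: float | None = None,
    reference_fps=None,
    reference_labels=None,
) -> ModelBundle:
    """Fit a final model. Continuous features are standardized with a scaler
    fitted here (stored in the bundle and re-applied at scoring time)."""
    x, kinds, fset = _as_matrix_kinds(features)
    y = _encode_labels(labels)

    scaler = None
    if fset is not None:
        scaler = fit_scaler(fset)
        x = apply_scaler(fset, scaler).matrix
    elif any(k == "continuous" for k in kinds):
        names = tuple(f"f{i}" for i in range(x.shape[1]))
        tmp = FeatureSet(list(names), x, kinds, [str(i) for i in range(len(x))])
        scaler = fit_scaler(tmp)
        x = apply_scaler(tmp, scaler).matrix

    est = _make_estimator(algorithm, hyperparameters, seed)
    est.fit(x, y)

    names = tuple(fset.names) if fset is not None else tuple(f"f{i}" for i in range(x.shape[1]))
    return ModelBundle(
        algorithm=algorithm,
        estimator=est,
        threshold=DEFAULT_THRESHOLDS[algorithm] if threshold is None else threshold,
        scaler=scaler,
        feature_names=names,
        feature_kinds=tuple(kinds),
        reference_fps=None if reference_fps is None else np.asarray(reference_fps),
        reference_labels=None if reference_labels is None else _encode_labels(reference_labels),
        seed=seed,
        hyperparameters=dict(hyperparameters),
    )


def score(model: ModelBundle, features) -> np.ndarray:
    """Score molecules with a fitted bundle (RF vote fraction / SVM margin)."""
    if isinstance(features, FeatureSet):
        if tuple(features.names) != model.feature_names:
            raise SchemaError("feature names do not match the training schema")
        x = apply_scaler(features, model.scaler).matrix if model.scaler else features.matrix
    else:
        x = np.asarray(features, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != len(model.feature_names):
            raise SchemaError(
                f"expected {len(model.feature_names)} features, got {x.shape[1]}"
            )
        if model.scaler is not None:
            c = model.scaler.continuous
            x = x.copy()
            x[:, c] = (x[:, c] - model.scaler.means[c]) / model.scaler.sds[c]
    return _raw_score(model.algorithm, model.estimator, x)
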