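"""Applicability domain and per-prediction reliability indicators.

Three heuristic indicators accompany every prediction:

* **mean k-NN similarity** — mean Tanimoto coefficient between the query and
  its k (default 5) nearest neighbors in the training set, computed in MACCS
  fingerprint space regardless of the model's own descriptor set. The query
  is *in domain* iff this mean is at or above ``ad_cutoff`` (default 0.5;
  a stricter 0.75 cutoff is also carried for high-confidence use).
* **threshold distance** — absolute distance between the model score and the
  decision threshold; small distances (below a per-algorithm margin: 0.15
  for RF vote fractions, 0.5 for SVM margins) indicate borderline calls.
* **concordant neighbors** — the number of consecutive nearest training
  neighbors whose activity class equals the predicted class; 0 means the
  nearest neighbor disagrees with the prediction.

Warnings: (a) ``low_similarity`` iff mean k-NN similarity < ad_cutoff
(strict <; the in-domain boundary itself is inclusive), (b) ``nn_conflict``
iff concordant_neighbors == 0, (c) ``low_margin`` iff threshold distance <
margin. These are heuristics, not validity guarantees.

A negative-Euclidean-distance neighbor space is available behind
``neighbor_metric="neg_euclidean"`` for completeness; it correlates poorly
with structural similarity and is not the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .features import FeaturizationError, compute_maccs
from .modeling import ModelBundle, classify
from .modeling import score as model_score

__all__ = [
    "ReliabilityConfig",
    "PredictionRecord",
    "tanimoto",
    "tanimoto_similarities",
    "mean_knn_similarity",
    "concordant_neighbors",
    "build_prediction_record",
    "assess",
    "assess_batch",
    "threshold_sweep",
    "binned_performance",
]

LOW_SIMILARITY = "low_similarity"
NN_CONFLICT = "nn_conflict"
LOW_MARGIN = "low_margin"


@dataclass(frozen=True)
class ReliabilityConfig:
    k_neighbors: int = 5
    ad_cutoff: float = 0.5
    ad_cutoff_strict: float = 0.75
    margin_warning: Mapping[str, float] = field(
        default_factory=lambda: {"rf": 0.15, "svm": 0.5}
    )
    neighbor_fingerprint: str = "maccs"
    neighbor_metric: str = "tanimoto"  # or "neg_euclidean" (non-default)

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        for c in (self.ad_cutoff, self.ad_cutoff_strict):
            if not 0.0 <= c <= 1.0:
                raise ValueError("AD cutoffs must lie in [0, 1]")
        if any(m <= 0 for m in self.margin_warning.values()):
            raise ValueError("margin warnings must be positive")

    def margin_for(self, algorithm: str) -> float:
        return self.margin_warning[algorithm]


@dataclass
class PredictionRecord:
    molecule_id: str
    score: float = math.nan
    predicted_class: int | None = None
    threshold_distance: float = math.nan
    mean_knn_similarity: float = math.nan
    concordant_neighbors: int = -1
    in_domain: bool = False
    warnings: frozenset = frozenset()
    featurization_failed: bool = False


def tanimoto(a, b) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| of two binary vectors.

    Two all-zero vectors are defined as dissimilar (0.0): a featureless
    molecule should not be declared close to anything, which is the
    conservative choice for applicability-domain purposes.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def tanimoto_similarities(query_fp, training_fps) -> np.ndarray:
    """Vector of Tanimoto coefficients between one query and each training
    fingerprint (rows of ``training_fps``)."""
    q = np.asarray(query_fp).astype(bool)
    t = np.asarray(training_fps).astype(bool)
    if t.ndim != 2 or t.shape[1] != q.shape[0]:
        raise ValueError("training fingerprints must be 2-D and match query length")
    inter = (t & q).sum(axis=1)
    union = (t | q).sum(axis=1)
    out = np.zeros(len(t), dtype=float)
    nz = union > 0
    out[nz] = inter[nz] / union[nz]
    return out


def _neighbor_similarities(query_fp, training_fps, metric: str) -> np.ndarray:
    if metric == "tanimoto":
        return tanimoto_similarities(query_fp, training_fps)
    if metric == "neg_euclidean":
        q = np.asarray(query_fp, dtype=float)
        t = np.asarray(training_fps, dtype=float)
        return -np.linalg.norm(t - q, axis=1)
    raise ValueError(f"unknown neighbor metric {metric!r}")


def _neighbor_order(sims: np.ndarray) -> np.ndarray:
    # descending similarity; ties broken by training-set index (stable)
    return np.argsort(-sims, kind="stable")


def mean_knn_similarity(query_fp, training_fps, k: int = 5, metric: str = "tanimoto") -> float:
    """Mean similarity of the k most similar training fingerprints."""
    sims = _neighbor_similarities(query_fp, training_fps, metric)
    if k > len(sims):
        raise ValueError(f"k={k} exceeds training-set size {len(sims)}")
    if k < 1:
        raise ValueError("k must be >= 1")
    order = _neighbor_order(sims)
    return float(sims[order[:k]].mean())


def concordant_neighbors(
    query_fp, predicted_class, training_fps, training_labels, metric: str = "tanimoto"
) -> int:
    """Number of consecutive nearest training neighbors carrying the
    predicted class; 0 if the nearest neighbor already disagrees."""
    labels = np.asarray(training_labels)
    if len(labels) == 0:
        raise ValueError("training set is empty")
    sims = _neighbor_similarities(query_fp, training_fps, metric)
    order = _neighbor_order(sims)
    count = 0
    for idx in order:
        if labels[idx] == predicted_class:
            count += 1
        else:
            break
    return count


def build_prediction_record(
    molecule_id: str,
    score_value: float,
    model: ModelBundle,
    query_fp,
    config: ReliabilityConfig | None = None,
) -> PredictionRecord:
    """Assemble the full reliability record from a score and a neighbor-space
    fingerprint, using the bundle's retained training fingerprints/labels."""
    config = config or ReliabilityConfig()
    if model.reference_fps is None:
        raise ValueError("model bundle carries no training reference data")
    predicted = classify(score_value, model.threshold)
    dist = abs(float(score_value) - model.threshold)
    knn = mean_knn_similarity(
        query_fp, model.reference_fps, config.k_neighbors, config.neighbor_metric
    )
    conc = concordant_neighbors(
        query_fp, predicted, model.reference_fps, model.reference_labels,
        config.neighbor_metric,
    )
    warnings = set()
    if knn < config.ad_cutoff:
        warnings.add(LOW_SIMILARITY)
    if conc == 0:
        warnings.add(NN_CONFLICT)
    if dist < config.margin_for(model.algorithm):
        warnings.add(LOW_MARGIN)
    return PredictionRecord(
        molecule_id=str(molecule_id),
        score=float(score_value),
        predicted_class=int(predicted),
        threshold_distance=dist,
        mean_knn_similarity=knn,
        concordant_neighbors=conc,
        in_domain=bool(knn >= config.ad_cutoff),
        warnings=frozenset(warnings),
    )


def assess(
    molecule_id: str,
    structure: str,
    model: ModelBundle,
    config: ReliabilityConfig | None = None,
    model_features=None,
) -> PredictionRecord:
    """Predict one molecule and attach all reliability indicators.

    ``model_features`` supplies the model-space feature vector; if omitted it
    must be derivable from the structure (MACCS-feature models only, where
    the neighbor fingerprint doubles as the model input). A featurization
    failure yields a record flagged ``featurization_failed`` and no
    prediction.
    """
    config = config or ReliabilityConfig()
    try:
        query_fp = compute_maccs(structure)
        if model_features is None:
            if len(model.feature_names) != len(query_fp):
                raise ValueError(
                    "model_features is required for models not built on MACCS keys"
                )
            model_features = query_fp
        s = float(model_score(model, np.asarray(model_features, dtype=float))[0])
    except FeaturizationError:
        return PredictionRecord(molecule_id=str(molecule_id), featurization_failed=True)
    return build_prediction_record(molecule_id, s, model, query_fp, config)


def assess_batch(
    molecule_ids: Sequence[str],
    structures: Sequence[str],
    model: ModelBundle,
    config: ReliabilityConfig | None = None,
) -> list[PredictionRecord]:
    return [
        assess(mid, smi, model, config) for mid, smi in zip(molecule_ids, structures)
    ]


def threshold_sweep(labels, scores, thresholds) -> pd.DataFrame:
    """Se/Sp/MCC (and the full measure set) at each decision threshold.

    As the threshold rises, sensitivity is non-increasing and specificity
    non-decreasing.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    y = labels if labels.dtype.kind in "ifub" else (labels == "sensitizer")
    y = np.asarray(y).astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    rows = []
    for t in thresholds:
        pred = classify(scores, float(t))
        m = _metrics.MetricsBundle.from_predictions(y, pred)
        rows.append({"threshold": float(t), **m.to_dict()})
    return pd.DataFrame(rows)


def _records_frame(records: Sequence[PredictionRecord], true_labels) -> pd.DataFrame:
    y = np.asarray(true_labels)
    if y.dtype.kind not in "ifub":
        y = (y == "sensitizer").astype(int)
    df = pd.DataFrame(
        {
            "molecule_id": [r.molecule_id for r in records],
            "predicted_class": [r.predicted_class for r in records],
            "mean_knn_similarity": [r.mean_knn_similarity for r in records],
            "threshold_distance": [r.threshold_distance for r in records],
            "concordant_neighbors": [r.concordant_neighbors for r in records],
            "score": [r.score for r in records],
            "true_label": y,
        }
    )
    return df


def binned_performance(
    records: Sequence[PredictionRecord],
    true_labels,
    bin_by: str,
    bin_edges: Sequence[float],
    cumulative: bool = False,
) -> pd.DataFrame:
    """Per-bin performance over a reliability indicator.

    ``bin_by`` is one of ``mean_knn_similarity``, ``threshold_distance`` or
    ``concordant_neighbors``. With ``cumulative=False`` the edges define
    disjoint half-open bins [e_i, e_{i+1}) (last bin closed above); with
    ``cumulative=True`` each edge defines a ">= edge" stratum plus one
    complementary "< first edge" stratum, the layout used for reporting
    AD/margin/concordance strata. Empty bins yield n=0 rows with NaN metrics.
    """
    if bin_by not in ("mean_knn_similarity", "threshold_distance", "concordant_neighbors"):
        raise ValueError(f"cannot bin by {bin_by!r}")
    df = _records_frame(records, true_labels)
    ok = df["predicted_class"].notna()
    df = df[ok]
    values = df[bin_by].to_numpy(dtype=float)

    strata: list[tuple[str, np.ndarray]] = []
    edges = list(bin_edges)
    if cumulative:
        for e in edges:
            strata.append((f">={e:g}", values >= e))
        strata.append((f"<{edges[0]:g}", values < edges[0]))
    else:
        if len(edges) < 2:
            raise ValueError("disjoint binning needs at least two edges")
        for lo, hi in zip(edges[:-1], edges[1:]):
            last = hi == edges[-1]
            mask = (values >= lo) & ((values <= hi) if last else (values < hi))
            strata.append((f"[{lo:g},{hi:g}{']' if last else ')'}", mask))

    rows = []
    for name, mask in strata:
        n = int(mask.sum())
        row = {"bin": name, "n": n}
        if n == 0:
            row.update({k: math.nan for k in ("MCC", "ACC", "AUC", "Se", "Sp", "PPV", "NPV", "CCR")})
            row["undefined"] = True
        else:
            sub = df[mask]
            m = _metrics.MetricsBundle.from_predictions(
                sub["true_label"].to_numpy(),
                sub["predicted_class"].to_numpy(dtype=int),
                scores=sub["score"].to_numpy(dtype=float),
            )
            d = m.to_dict()
            d.pop("n")
            row.update(d)
            row["undefined"] = bool(m.undefined)
        rows.append(row)
    return pd.DataFrame(rows)
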