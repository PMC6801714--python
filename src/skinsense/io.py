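"""Readers and writers for all pipeline artifacts, plus run configuration.

CSV with columns ``id,smiles,label[,source]`` is the canonical interchange
format for raw molecule records; SDF (v2000) is supported for input, taking
the activity label from a named property. Curated sets, curation logs,
feature sets (dense CSV with a JSON sidecar schema), prediction reports and
fitted model bundles all round-trip through this module.

All randomness in a run flows from a single top-level seed expanded per
pipeline stage by name hashing (:func:`stage_seed`), so each stage is
independently reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from rdkit import Chem

from .curation import CurationLog, CuratedRecord, RawRecord
from .features import FeatureSet
from .modeling import ModelBundle
from .reliability import PredictionRecord

__all__ = [
    "RunConfig",
    "stage_seed",
    "read_raw_csv",
    "write_raw_csv",
    "read_raw_sdf",
    "write_curated_csv",
    "read_curated_csv",
    "write_curation_log",
    "read_curation_log",
    "write_feature_set",
    "read_feature_set",
    "write_prediction_report",
    "read_prediction_report",
    "save_bundle",
    "load_bundle",
]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed below 2**31 from one top-level seed."""
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Validated configuration for an end-to-end modeling run."""

    seed: int = 43
    algorithm: str = "rf"
    feature_kinds: tuple[str, ...] = ("maccs",)
    test_fraction: float = 0.2
    folds: int = 10
    k_neighbors: int = 5
    ad_cutoff: float = 0.5
    threshold: float | None = None
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.algorithm not in ("rf", "svm"):
            raise ValueError("algorithm must be 'rf' or 'svm'")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        known = {"maccs", "morgan2", "physchem", "alerts"}
        unknown = set(self.feature_kinds) - known
        if unknown:
            raise ValueError(f"unknown feature kinds: {sorted(unknown)}")

    def stage_seed(self, stage: str) -> int:
        return stage_seed(self.seed, stage)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        data["feature_kinds"] = tuple(data.get("feature_kinds", ("maccs",)))
        return cls(**data)


# ---------------------------------------------------------------- raw records


def read_raw_csv(path, source: str | None = None) -> list[RawRecord]:
    """Read raw records from CSV with required header id,smiles,label[,source]."""
    df = pd.read_csv(path, dtype=str)
    required = {"id", "smiles", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required CSV columns: {sorted(missing)}")
    default = source or Path(str(path)).stem
    return [
        RawRecord(
            record_id=row["id"],
            structure=row["smiles"],
            label=row["label"],
            source=row.get("source") or default,
        )
        for _, row in df.iterrows()
    ]


def write_raw_csv(records: Sequence[RawRecord], path) -> None:
    pd.DataFrame(
        {
            "id": [r.record_id for r in records],
            "smiles": [r.structure for r in records],
            "label": [r.label for r in records],
            "source": [r.source for r in records],
        }
    ).to_csv(path, index=False)


def read_raw_sdf(path, label_prop: str, id_prop: str | None = None,
                 source: str | None = None) -> list[RawRecord]:
    """Read raw records from an SDF file, labels from a named property."""
    default = source or Path(str(path)).stem
    records = []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            # unreadable entry: emit an unparseable placeholder so curation
            # can count it as invalid instead of silently dropping it
            records.append(RawRecord(f"sdf-{i}", "", "unknown", default))
            continue
        if not mol.HasProp(label_prop):
            raise ValueError(f"SDF record {i} lacks label property {label_prop!r}")
        rid = (
            mol.GetProp(id_prop)
            if id_prop and mol.HasProp(id_prop)
            else (mol.GetProp("_Name") or f"sdf-{i}")
        )
        records.append(
            RawRecord(rid, Chem.MolToSmiles(mol), mol.GetProp(label_prop), default)
        )
    return records


# ------------------------------------------------------------- curated output


def write_curated_csv(records: Sequence[CuratedRecord], path) -> None:
    pd.DataFrame(
        {
            "canonical_smiles": [r.canonical_structure for r in records],
            "label": [r.label for r in records],
            "provenance": [
                ";".join(f"{s}:{i}" for s, i in r.provenance) for r in records
            ],
        }
    ).to_csv(path, index=False)


def read_curated_csv(path) -> list[CuratedRecord]:
    df = pd.read_csv(path, dtype=str)
    out = []
    for _, row in df.iterrows():
        prov = tuple(
            tuple(item.split(":", 1)) for item in str(row["provenance"]).split(";") if item
        )
        out.append(CuratedRecord(row["canonical_smiles"], row["label"], prov))
    return out


def write_curation_log(log: CurationLog, path) -> None:
    Path(path).write_text(json.dumps(log.to_dict(), indent=2))


def read_curation_log(path) -> CurationLog:
    return CurationLog(**json.loads(Path(path).read_text()))


# --------------------------------------------------------------- feature sets


def write_feature_set(fs: FeatureSet, path) -> None:
    """Dense CSV plus a JSON sidecar schema (names, kinds, set name)."""
    path = Path(path)
    fs.to_frame().to_csv(path, index_label="molecule_id")
    schema = {"names": list(fs.names), "kinds": list(fs.kinds), "set_name": fs.set_name}
    path.with_suffix(path.suffix + ".schema.json").write_text(json.dumps(schema))


def read_feature_set(path) -> FeatureSet:
    path = Path(path)
    schema = json.loads(path.with_suffix(path.suffix + ".schema.json").read_text())
    df = pd.read_csv(path, index_col="molecule_id")
    if list(df.columns) != schema["names"]:
        raise ValueError("feature CSV columns do not match sidecar schema")
    return FeatureSet(
        names=schema["names"],
        matrix=df.to_numpy(dtype=float),
        kinds=schema["kinds"],
        molecule_ids=[str(i) for i in df.index],
        set_name=schema["set_name"],
    )


# --------------------------------------------------------- prediction reports

_REPORT_COLUMNS = [
    "molecule_id",
    "in_domain",
    "predicted_class",
    "score",
    "threshold",
    "threshold_distance",
    "mean_knn_similarity",
    "concordant_neighbors",
    "warnings",
    "featurization_failed",
]


def write_prediction_report(
    records: Sequence[PredictionRecord], path, threshold: float
) -> None:
    """Per-molecule reliability report: AD flag, class, threshold distance,
    mean k-NN similarity, concordant-neighbor count and warnings."""
    rows = []
    for r in records:
        rows.append(
            {
                "molecule_id": r.molecule_id,
                "in_domain": r.in_domain,
                "predicted_class": "" if r.predicted_class is None else r.predicted_class,
                "score": r.score,
                "threshold": threshold,
                "threshold_distance": r.threshold_distance,
                "mean_knn_similarity": r.mean_knn_similarity,
                "concordant_neighbors": r.concordant_neighbors,
                "warnings": ";".join(sorted(r.warnings)),
                "featurization_failed": r.featurization_failed,
            }
        )
    pd.DataFrame(rows, columns=_REPORT_COLUMNS).to_csv(path, index=False)


def read_prediction_report(path) -> list[PredictionRecord]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        failed = bool(row["featurization_failed"])
        pred = row["predicted_class"]
        out.append(
            PredictionRecord(
                molecule_id=str(row["molecule_id"]),
                score=float(row["score"]),
                predicted_class=None if pd.isna(pred) else int(pred),
                threshold_distance=float(row["threshold_distance"]),
                mean_knn_similarity=float(row["mean_knn_similarity"]),
                concordant_neighbors=int(row["concordant_neighbors"]),
                in_domain=bool(row["in_domain"]),
                warnings=frozenset(
                    w for w in str(row["warnings"]).split(";")
                    if w and w != "nan"
                ),
                featurization_failed=failed,
            )
        )
    return out


# ---------------------------------------------------------------- model store

_BUNDLE_FORMAT_VERSION = 1


def save_bundle(bundle: ModelBundle, path) -> None:
    """Persist a fitted model bundle (versioned joblib archive)."""
    joblib.dump({"format_version": _BUNDLE_FORMAT_VERSION, "bundle": bundle}, path)


def load_bundle(path) -> ModelBundle:
    payload = joblib.load(path)
    if payload.get("format_version") != _BUNDLE_FORMAT_VERSION:
        raise ValueError("unsupported model bundle format")
    return payload["bundle"]
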