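"""Fingerprints and descriptors: MACCS keys, Morgan2, an interpretable
physicochemical set, and the 5-bit mechanistic protein-binding-alert
fingerprint, plus train-fitted standard scaling and feature-set algebra.

The alert fingerprint is the package's mechanistic-domain descriptor: each of
its five bits records whether any substructure pattern of one electrophilic
reaction domain (Michael addition, SN2 reaction, Schiff base formation,
acylation, nucleophilic addition) matches the molecule. The pattern library
ships as editable YAML configuration (:data:`DEFAULT_ALERTS_PATH`).

The 53-descriptor physicochemical set is an open, RDKit-backed analog of the
interpretable 2D descriptor subsets used with commercial engines; it makes no
claim of numeric identity with any closed implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem, rdBase
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator

__all__ = [
    "PHYSCHEM_53",
    "DEFAULT_ALERT_DOMAINS",
    "DescriptorConfig",
    "AlertLibrary",
    "FeatureSet",
    "ScalerParams",
    "FeaturizationError",
    "AlertConfigError",
    "SchemaError",
    "compute_maccs",
    "compute_morgan",
    "compute_physchem",
    "compute_alert_fingerprint",
    "build_feature_set",
    "fit_scaler",
    "apply_scaler",
    "invert_scaler",
    "concatenate_features",
]

#: 53 interpretable physicochemical/topological descriptors (RDKit names):
#: size and composition, H-bonding, lipophilicity, polarity, ring/aromaticity
#: counts, connectivity and shape indices.
PHYSCHEM_53: tuple[str, ...] = (
    "MolWt", "HeavyAtomMolWt", "ExactMolWt", "NumValenceElectrons",
    "FractionCSP3", "HeavyAtomCount", "NHOHCount", "NOCount",
    "NumHAcceptors", "NumHDonors", "NumHeteroatoms", "NumRotatableBonds",
    "NumAromaticRings", "NumSaturatedRings", "NumAliphaticRings",
    "NumAromaticCarbocycles", "NumAromaticHeterocycles",
    "NumSaturatedCarbocycles", "NumSaturatedHeterocycles",
    "NumAliphaticCarbocycles", "NumAliphaticHeterocycles", "RingCount",
    "MolLogP", "MolMR", "TPSA", "LabuteASA", "BalabanJ", "BertzCT",
    "Chi0", "Chi0n", "Chi0v", "Chi1", "Chi1n", "Chi1v", "Chi2n", "Chi2v",
    "Chi3n", "Chi3v", "Chi4n", "Chi4v", "HallKierAlpha",
    "Kappa1", "Kappa2", "Kappa3", "NumRadicalElectrons",
    "MaxEStateIndex", "MinEStateIndex", "MaxAbsEStateIndex",
    "MinAbsEStateIndex", "FpDensityMorgan1", "FpDensityMorgan2",
    "FpDensityMorgan3", "qed",
)

DEFAULT_ALERT_DOMAINS: tuple[str, ...] = (
    "michael_addition",
    "sn2_reaction",
    "schiff_base_formation",
    "acylation",
    "nucleophilic_addition",
)

DEFAULT_ALERTS_PATH = resources.files("skinsense.data") / "alerts.yaml"

_DESCRIPTOR_FNS = dict(Descriptors._descList)


class FeaturizationError(ValueError):
    """Descriptor or fingerprint calculation failed for a molecule."""


class AlertConfigError(ValueError):
    """The alert library configuration is invalid (e.g. bad SMARTS)."""


class SchemaError(ValueError):
    """Feature names/ids do not match the expected schema."""


@dataclass(frozen=True)
class DescriptorConfig:
    morgan_radius: int = 2
    morgan_nbits: int = 2048
    physchem_set: tuple[str, ...] = PHYSCHEM_53
    maccs_nkeys: int = 166

    def __post_init__(self) -> None:
        n = self.morgan_nbits
        if n < 1 or (n & (n - 1)) != 0:
            raise ValueError("morgan_nbits must be a power of two")
        if not self.physchem_set:
            raise ValueError("physchem_set must be non-empty")
        if len(set(self.physchem_set)) != len(self.physchem_set):
            raise ValueError("physchem_set contains duplicates")
        unknown = [d for d in self.physchem_set if d not in _DESCRIPTOR_FNS]
        if unknown:
            raise ValueError(f"unknown descriptors: {unknown}")


class AlertLibrary:
    """Ordered mechanistic domains, each a list of SMARTS patterns.

    The domain order is fixed and defines the bit order of the alert
    fingerprint. SMARTS are compiled at load time; an invalid pattern raises
    :class:`AlertConfigError` immediately.
    """

    def __init__(self, domains: Sequence[tuple[str, Sequence[str]]]):
        if not domains:
            raise AlertConfigError("alert library has no domains")
        self.domains: list[tuple[str, list[str]]] = []
        self._compiled: list[list[Chem.Mol]] = []
        for name, patterns in domains:
            patterns = list(patterns)
            if not patterns:
                raise AlertConfigError(f"domain {name!r} has no patterns")
            compiled = []
            for p in patterns:
                q = Chem.MolFromSmarts(p)
                if q is None:
                    raise AlertConfigError(f"invalid SMARTS in domain {name!r}: {p!r}")
                compiled.append(q)
            self.domains.append((name, patterns))
            self._compiled.append(compiled)

    @property
    def domain_names(self) -> list[str]:
        return [name for name, _ in self.domains]

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    @classmethod
    def from_yaml(cls, path_or_text) -> "AlertLibrary":
        if hasattr(path_or_text, "read_text"):
            text = path_or_text.read_text()
        else:
            with open(path_or_text, "r", encoding="utf-8") as fh:
                text = fh.read()
        data = yaml.safe_load(text)
        try:
            domains = [(d["name"], list(d["smarts"])) for d in data["domains"]]
        except (KeyError, TypeError) as exc:
            raise AlertConfigError(f"malformed alert library: {exc}") from exc
        return cls(domains)

    def to_yaml(self, path) -> None:
        data = {"domains": [{"name": n, "smarts": p} for n, p in self.domains]}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def default(cls) -> "AlertLibrary":
        return cls.from_yaml(DEFAULT_ALERTS_PATH)

    def match(self, mol: Chem.Mol) -> np.ndarray:
        bits = np.zeros(self.n_domains, dtype=np.uint8)
        for i, compiled in enumerate(self._compiled):
            if any(mol.HasSubstructMatch(q) for q in compiled):
                bits[i] = 1
        return bits


def _parse(structure: str) -> Chem.Mol:
    with rdBase.BlockLogs():
        mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise FeaturizationError(f"unparseable SMILES: {structure!r}")
    return mol


def compute_maccs(structure: str) -> np.ndarray:
    """166 MACCS structural keys (slot 0 of the 167-slot vector is unused
    by the toolkit and is dropped)."""
    fp = MACCSkeys.GenMACCSKeys(_parse(structure))
    arr = np.zeros(167, dtype=np.uint8)
    for b in fp.GetOnBits():
        arr[b] = 1
    return arr[1:]


def compute_morgan(structure: str, config: DescriptorConfig | None = None) -> np.ndarray:
    """Hashed circular (Morgan) fingerprint folded to ``config.morgan_nbits``."""
    config = config or DescriptorConfig()
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=config.morgan_radius, fpSize=config.morgan_nbits
    )
    fp = gen.GetFingerprint(_parse(structure))
    arr = np.zeros(config.morgan_nbits, dtype=np.uint8)
    for b in fp.GetOnBits():
        arr[b] = 1
    return arr


def compute_physchem(structure: str, config: DescriptorConfig | None = None) -> np.ndarray:
    """Continuous physicochemical descriptor vector for one molecule."""
    config = config or DescriptorConfig()
    mol = _parse(structure)
    vals = np.empty(len(config.physchem_set), dtype=float)
    for i, name in enumerate(config.physchem_set):
        try:
            v = float(_DESCRIPTOR_FNS[name](mol))
        except Exception as exc:  # rdkit raises assorted exceptions
            raise FeaturizationError(f"descriptor {name} failed on {structure!r}") from exc
        if not math.isfinite(v):
            raise FeaturizationError(f"descriptor {name} non-finite on {structure!r}")
        vals[i] = v
    return vals


def compute_alert_fingerprint(structure: str, library: AlertLibrary | None = None) -> np.ndarray:
    """5-bit mechanistic-domain fingerprint: bit d is 1 iff any pattern of
    domain d matches; bit order is the library's domain order."""
    library = library or AlertLibrary.default()
    return library.match(_parse(structure))


@dataclass
class FeatureSet:
    """A named, aligned feature matrix (molecules x features)."""

    names: list[str]
    matrix: np.ndarray
    kinds: list[str]  # "binary" | "continuous" per feature
    molecule_ids: list[str]
    set_name: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        n, m = self.matrix.shape
        if len(self.names) != m or len(self.kinds) != m:
            raise ValueError("names/kinds length must equal n_features")
        if len(self.molecule_ids) != n:
            raise ValueError("molecule_ids length must equal n_molecules")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if np.isnan(self.matrix).any():
            raise ValueError("feature matrix contains missing values")
        for j, kind in enumerate(self.kinds):
            if kind == "binary" and not np.isin(self.matrix[:, j], (0.0, 1.0)).all():
                raise ValueError(f"binary feature {self.names[j]!r} has non 0/1 values")

    @property
    def n_molecules(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.molecule_ids, columns=self.names)

    def subset(self, row_indices) -> "FeatureSet":
        idx = np.asarray(row_indices)
        return FeatureSet(
            names=list(self.names),
            matrix=self.matrix[idx],
            kinds=list(self.kinds),
            molecule_ids=[self.molecule_ids[i] for i in idx],
            set_name=self.set_name,
        )


_KIND_DISPATCH = {
    "maccs": (compute_maccs, "binary"),
    "morgan2": (compute_morgan, "binary"),
    "physchem": (compute_physchem, "continuous"),
    "alerts": (compute_alert_fingerprint, "binary"),
}


def build_feature_set(
    molecule_ids: Sequence[str],
    structures: Sequence[str],
    kind: str,
    config: DescriptorConfig | None = None,
    library: AlertLibrary | None = None,
) -> tuple[FeatureSet, list[str]]:
    """Featurize a batch of structures; failed molecules are excluded from
    the matrix and returned as a list of flagged ids."""
    if kind not in _KIND_DISPATCH:
        raise ValueError(f"unknown feature kind {kind!r}; choose from {sorted(_KIND_DISPATCH)}")
    if len(molecule_ids) != len(structures):
        raise ValueError("molecule_ids and structures must align")
    config = config or DescriptorConfig()
    fn, feat_kind = _KIND_DISPATCH[kind]

    rows, kept_ids, failed = [], [], []
    for mid, smi in zip(molecule_ids, structures):
        try:
            if kind == "maccs":
                rows.append(fn(smi))
            elif kind == "alerts":
                rows.append(fn(smi, library))
            else:
                rows.append(fn(smi, config))
            kept_ids.append(str(mid))
        except FeaturizationError:
            failed.append(str(mid))

    if kind == "maccs":
        names = [f"maccs_{i}" for i in range(1, config.maccs_nkeys + 1)]
    elif kind == "morgan2":
        names = [f"morgan_{i}" for i in range(config.morgan_nbits)]
    elif kind == "physchem":
        names = list(config.physchem_set)
    else:
        names = list((library or AlertLibrary.default()).domain_names)

    matrix = np.vstack(rows) if rows else np.empty((0, len(names)))
    fs = FeatureSet(
        names=names,
        matrix=matrix,
        kinds=[feat_kind] * len(names),
        molecule_ids=kept_ids,
        set_name=kind,
    )
    return fs, failed


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature means/sds fitted on training data (continuous features
    only; binary features pass through unscaled). Zero-variance columns use
    sd = 1, so a constant column scales to all zeros."""

    names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    continuous: np.ndarray  # boolean mask over names

    def __post_init__(self) -> None:
        if (self.sds < 0).any():
            raise ValueError("standard deviations must be >= 0")


def fit_scaler(train: FeatureSet) -> ScalerParams:
    cont = np.array([k == "continuous" for k in train.kinds])
    means = np.zeros(train.n_features)
    sds = np.ones(train.n_features)
    if cont.any():
        x = train.matrix[:, cont]
        means[cont] = x.mean(axis=0)
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0.0] = 1.0  # constant column -> scaled to zeros
        sds[cont] = sd
    return ScalerParams(tuple(train.names), means, sds, cont)


def _check_schema(features: FeatureSet, params: ScalerParams) -> None:
    if tuple(features.names) != params.names:
        raise SchemaError("feature names do not match scaler schema")


def apply_scaler(features: FeatureSet, params: ScalerParams) -> FeatureSet:
    _check_schema(features, params)
    mat = features.matrix.copy()
    c = params.continuous
    mat[:, c] = (mat[:, c] - params.means[c]) / params.sds[c]
    return FeatureSet(
        list(features.names), mat, list(features.kinds),
        list(features.molecule_ids), features.set_name,
    )


def invert_scaler(features: FeatureSet, params: ScalerParams) -> FeatureSet:
    _check_schema(features, params)
    mat = features.matrix.copy()
    c = params.continuous
    mat[:, c] = mat[:, c] * params.sds[c] + params.means[c]
    return FeatureSet(
        list(features.names), mat, list(features.kinds),
        list(features.molecule_ids), features.set_name,
    )


def concatenate_features(a: FeatureSet, b: FeatureSet) -> FeatureSet:
    """Column-wise concatenation of two aligned feature sets.

    Molecule ids must be identical and in identical order. On a feature-name
    collision both sides' names are prefixed with their set names.
    """
    if a.n_features == 0:
        return b
    if b.n_features == 0:
        return a
    if a.molecule_ids != b.molecule_ids:
        raise SchemaError("molecule ids do not align between feature sets")
    names_a, names_b = list(a.names), list(b.names)
    if set(names_a) & set(names_b):
        names_a = [f"{a.set_name or 'a'}.{n}" for n in names_a]
        names_b = [f"{b.set_name or 'b'}.{n}" for n in names_b]
        if set(names_a) & set(names_b):
            raise SchemaError("feature names collide even after prefixing")
    set_name = "+".join(s for s in (a.set_name, b.set_name) if s)
    return FeatureSet(
        names=names_a + names_b,
        matrix=np.hstack([a.matrix, b.matrix]),
        kinds=list(a.kinds) + list(b.kinds),
        molecule_ids=list(a.molecule_ids),
        set_name=set_name,
    )
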