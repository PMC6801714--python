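"""Self-contained synthetic datasets for exercising every stage of the
pipeline without external downloads.

Two generators are provided:

* :func:`generate_molecules` emits LLNA-style raw records built from seven
  programmatic structure families — alkyl-chain and aromatic non-sensitizers
  plus one family per mechanistic alert domain (Michael acceptors, SN2
  electrophiles, Schiff-base-forming aldehydes, acylating acid chlorides and
  quinone-type nucleophilic-addition electrophiles). Salt forms, exact
  duplicates, engineered label conflicts, ambiguous salt records and invalid
  structures are injected at stated rates, and every injected anomaly is
  recorded in a manifest whose expected curation log the curation module must
  reproduce exactly.
* :func:`generate_features` emits clustered Gaussian class-conditional
  feature data in which test labels are flipped with a probability that
  increases with the point's displacement from the training data — the
  statistical structure the reliability analyses assume (far-from-training
  predictions are noisier). Classes are organized in several compact clusters
  (emulating chemical series, where structural neighbors share activity), so
  nearest-neighbor class concordance is informative by construction.
  :func:`grid_fingerprints` converts the continuous features into sparse
  binary vectors (one-hot bin per dimension, emulating substructure keys)
  whose Tanimoto similarity decays with Euclidean distance, for exercising
  the fingerprint-based neighbor machinery.

No toxicological realism is claimed; the fixtures exist to exercise code
paths and statistical structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .curation import CurationLog, RawRecord

__all__ = [
    "ALERT_FAMILIES",
    "NON_SENSITIZER_FAMILIES",
    "SyntheticMoleculeSpec",
    "SyntheticFeatureSpec",
    "SyntheticFeatureData",
    "generate_molecules",
    "generate_features",
    "grid_fingerprints",
]

#: Families carrying a protein-binding alert, keyed by the alert-library
#: domain their members must light up.
ALERT_FAMILIES: Mapping[str, str] = {
    "michael_acceptor": "michael_addition",
    "sn2_electrophile": "sn2_reaction",
    "aldehyde": "schiff_base_formation",
    "acyl_halide": "acylation",
    "quinone": "nucleophilic_addition",
}

NON_SENSITIZER_FAMILIES: tuple[str, ...] = ("alkyl_chain", "aromatic")

ALL_FAMILIES: tuple[str, ...] = NON_SENSITIZER_FAMILIES + tuple(ALERT_FAMILIES)

#: SMILES builders per family; ``k`` >= 1 varies an alkyl chain so every
#: member of a family is a distinct canonical structure (chain homologs).
_FAMILY_BUILDERS = {
    "alkyl_chain": lambda k: "C" * (k + 2),
    "aromatic": lambda k: "c1ccccc1" + "C" * k,
    "michael_acceptor": lambda k: "C=CC(=O)" + "C" * k,
    "sn2_electrophile": lambda k: ("C" * k + "CBr") if k % 2 else ("C" * k + "C1CO1"),
    "aldehyde": lambda k: "C" * k + "C=O",
    "acyl_halide": lambda k: "C" * k + "C(=O)Cl",
    "quinone": lambda k: "O=C1C=CC(=O)C(" + "C" * k + ")=C1",
}

#: Benign carbon-free counterions: the largest-organic-component rule always
#: recovers the parent structure from these salt forms.
_COUNTERIONS = (".Cl", ".O", ".[Na+]")

_POTENCY_CLASSES = ("weak", "moderate", "strong", "extreme")


@dataclass(frozen=True)
class SyntheticMoleculeSpec:
    """Stated world for the molecular generator.

    Defaults give every mechanistic domain at least 25 instances (so the
    alert fingerprint is learnable) and inject no anomalies; anomaly rates
    are opt-in per test.
    """

    n_per_family: Mapping[str, int] = field(
        default_factory=lambda: {f: 25 for f in ALL_FAMILIES}
    )
    label_noise: float = 0.0
    salt_fraction: float = 0.0
    duplicate_fraction: float = 0.0
    conflict_fraction: float = 0.0
    n_ambiguous_salts: int = 0
    n_invalid: int = 0
    seed: int = 43

    def __post_init__(self) -> None:
        if not 0.0 <= self.label_noise <= 0.5:
            raise ValueError("label_noise must lie in [0, 0.5]")
        for name in ("salt_fraction", "duplicate_fraction", "conflict_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if any(n < 0 for n in self.n_per_family.values()):
            raise ValueError("family counts must be >= 0")
        unknown = set(self.n_per_family) - set(ALL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown families: {sorted(unknown)}")
        if self.n_ambiguous_salts < 0 or self.n_invalid < 0:
            raise ValueError("anomaly counts must be >= 0")


def _raw_label(rng: np.random.Generator, sensitizer: bool) -> str:
    """Source-vocabulary label: LLNA potency class or 'negative'."""
    if sensitizer:
        return str(rng.choice(_POTENCY_CLASSES))
    return "negative"


def generate_molecules(
    spec: SyntheticMoleculeSpec | None = None,
) -> tuple[list[RawRecord], dict]:
    """Generate raw molecule records plus a ground-truth manifest.

    The manifest's ``expected_log`` field holds the exact
    :class:`~skinsense.curation.CurationLog` counts that curating the records
    must produce: duplicates follow the records-minus-unique-structures
    convention (so each engineered conflict also contributes one duplicate),
    conflict structures count once each, and every conflicting structure
    disappears from the output.
    """
    spec = spec or SyntheticMoleculeSpec()
    rng = np.random.default_rng(spec.seed)

    base: list[RawRecord] = []
    for family in ALL_FAMILIES:
        n = spec.n_per_family.get(family, 0)
        build = _FAMILY_BUILDERS[family]
        is_sens = family in ALERT_FAMILIES
        for k in range(1, n + 1):
            label_is_sens = is_sens
            if spec.label_noise > 0 and rng.random() < spec.label_noise:
                label_is_sens = not label_is_sens
            base.append(
                RawRecord(
                    record_id=f"{family}-{k:03d}",
                    structure=build(k),
                    label=_raw_label(rng, label_is_sens),
                    source="synthetic",
                )
            )

    n_base = len(base)
    records = list(base)

    # salt forms: in-place benign counterions; curation recovers the parent
    n_salts = int(spec.salt_fraction * n_base)
    salt_idx = rng.choice(n_base, size=n_salts, replace=False) if n_salts else []
    for i in salt_idx:
        r = records[i]
        ion = _COUNTERIONS[int(rng.integers(len(_COUNTERIONS)))]
        records[i] = RawRecord(r.record_id, r.structure + ion, r.label, r.source)

    # duplicates and conflicts target disjoint base structures so the
    # expected bookkeeping stays exact
    n_dup = int(spec.duplicate_fraction * n_base)
    n_conf = int(spec.conflict_fraction * n_base)
    if n_dup + n_conf > n_base:
        raise ValueError("duplicate_fraction + conflict_fraction exceed the base set")
    chosen = rng.choice(n_base, size=n_dup + n_conf, replace=False) if n_dup + n_conf else []
    dup_idx, conf_idx = chosen[:n_dup], chosen[n_dup:]

    for j, i in enumerate(dup_idx):
        r = records[i]
        records.append(RawRecord(f"dup-{j:03d}", r.structure, r.label, "synthetic-dup"))
    for j, i in enumerate(conf_idx):
        r = records[i]
        flipped = "negative" if r.label != "negative" else str(rng.choice(_POTENCY_CLASSES))
        records.append(RawRecord(f"conflict-{j:03d}", r.structure, flipped, "synthetic-conflict"))

    # ambiguous salts: two non-identical organic components of equal heavy-
    # atom count (hexane-homolog . alkanol), rejected by the salt filter
    for j in range(spec.n_ambiguous_salts):
        k = 5 + j
        records.append(
            RawRecord(
                f"ambiguous-{j:03d}",
                "C" * k + "." + "C" * (k - 1) + "O",
                "negative",
                "synthetic-ambiguous",
            )
        )

    for j in range(spec.n_invalid):
        records.append(
            RawRecord(f"invalid-{j:03d}", "C(" + ")" * 0, "negative", "synthetic-invalid")
        )

    order = rng.permutation(len(records))
    records = [records[i] for i in order]

    expected_log = CurationLog(
        n_input=len(records),
        n_salt_ambiguous=spec.n_ambiguous_salts,
        n_invalid=spec.n_invalid,
        n_duplicates_removed=n_dup + n_conf,
        n_conflicts_removed=n_conf,
        n_output=n_base - n_conf,
    )
    manifest = {
        "n_base": n_base,
        "n_records": len(records),
        "n_duplicates": n_dup,
        "n_conflicts": n_conf,
        "n_salt_forms": n_salts,
        "n_ambiguous_salts": spec.n_ambiguous_salts,
        "n_invalid": spec.n_invalid,
        "seed": spec.seed,
        "expected_log": expected_log,
    }
    return records, manifest


@dataclass(frozen=True)
class SyntheticFeatureSpec:
    """Stated world for the feature-space generator.

    ``n_clusters`` compact Gaussian clusters (centers ~ N(0, center_scale^2),
    within-cluster sd ``within_sd``) are assigned alternating classes, so
    points that are close in feature space share a class — the
    structure-activity continuity that makes nearest-neighbor concordance
    meaningful. A ``far_fraction`` of test points is displaced from its
    cluster by a remoteness ``r ~ U(remoteness_lo, remoteness_hi)`` along a
    random diagonal direction, and each test point's observed label flips
    with probability ``min(flip_base + flip_slope * r, 0.5)`` — label noise
    that grows with distance from the training data.
    """

    n_train: int = 400
    n_test: int = 200
    n_features: int = 10
    n_clusters: int = 8
    center_scale: float = 2.5
    within_sd: float = 0.7
    far_fraction: float = 0.4
    remoteness_lo: float = 1.0
    remoteness_hi: float = 6.0
    flip_base: float = 0.02
    flip_slope: float = 0.12
    seed: int = 43

    def __post_init__(self) -> None:
        if self.n_train < 4 or self.n_test < 1:
            raise ValueError("need at least 4 training and 1 test point")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.n_clusters < 2 or self.n_clusters % 2:
            raise ValueError("n_clusters must be an even number >= 2")
        if not 0.0 <= self.far_fraction <= 1.0:
            raise ValueError("far_fraction must lie in [0, 1]")
        if not 0.0 <= self.flip_base <= 0.5:
            raise ValueError("flip_base must lie in [0, 0.5]")
        if self.flip_slope < 0 or self.within_sd <= 0 or self.center_scale <= 0:
            raise ValueError("flip_slope >= 0 and positive scales required")
        if not 0 <= self.remoteness_lo <= self.remoteness_hi:
            raise ValueError("need 0 <= remoteness_lo <= remoteness_hi")


@dataclass
class SyntheticFeatureData:
    x_train: np.ndarray
    y_train: np.ndarray
    x_test: np.ndarray
    y_test: np.ndarray  # observed (possibly flipped) labels
    y_test_true: np.ndarray
    remoteness: np.ndarray  # displacement magnitude per test point
    flip_prob: np.ndarray  # per test point


def generate_features(spec: SyntheticFeatureSpec | None = None) -> SyntheticFeatureData:
    """Clustered class-conditional features with distance-dependent test
    label noise; deterministic for a fixed seed."""
    spec = spec or SyntheticFeatureSpec()
    rng = np.random.default_rng(spec.seed)
    p = spec.n_features

    centers = rng.standard_normal((spec.n_clusters, p)) * spec.center_scale
    cluster_class = np.arange(spec.n_clusters) % 2

    def draw(n: int) -> tuple[np.ndarray, np.ndarray]:
        c = rng.integers(0, spec.n_clusters, size=n)
        x = centers[c] + rng.standard_normal((n, p)) * spec.within_sd
        return x, cluster_class[c]

    x_train, y_train = draw(spec.n_train)
    x_test, y_true = draw(spec.n_test)

    far = rng.random(spec.n_test) < spec.far_fraction
    r = np.where(
        far, rng.uniform(spec.remoteness_lo, spec.remoteness_hi, spec.n_test), 0.0
    )
    direction = rng.choice([-1.0, 1.0], size=(spec.n_test, p)) / np.sqrt(p)
    x_test = x_test + r[:, None] * direction

    flip_prob = np.clip(spec.flip_base + spec.flip_slope * r, 0.0, 0.5)
    flips = rng.random(spec.n_test) < flip_prob
    y_test = np.where(flips, 1 - y_true, y_true)

    return SyntheticFeatureData(x_train, y_train, x_test, y_test, y_true, r, flip_prob)


def grid_fingerprints(
    x: np.ndarray, bin_width: float = 1.0, limit: float = 6.0
) -> np.ndarray:
    """Sparse binary encoding of continuous features: one-hot bin per
    dimension (values clipped to [-limit, limit]).

    Each vector has exactly ``n_features`` bits on, so the Tanimoto
    coefficient between two encodings decays from 1 (all bins shared) to 0
    (no bin shared) as points move apart — a stand-in for substructure-key
    fingerprints when exercising the neighbor-based reliability machinery on
    feature-space data.
    """
    x = np.asarray(x, dtype=float)
    edges = np.arange(-limit, limit + bin_width / 2, bin_width)
    n_bins = len(edges) - 1
    xi = np.clip(x, -limit, np.nextafter(limit, -np.inf))
    idx = np.digitize(xi, edges) - 1
    n, p = x.shape
    out = np.zeros((n, p * n_bins), dtype=np.uint8)
    rows = np.repeat(np.arange(n), p)
    cols = (np.tile(np.arange(p), (n, 1)) * n_bins + idx).ravel()
    out[rows, cols] = 1
    return out
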