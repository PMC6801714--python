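"""Molecule standardization, label mapping, deduplication and set merging.

Raw records from heterogeneous sources (LLNA-style compilations with potency
vocabularies, or already-binary labels) are brought onto a single canonical
footing:

1. keep the largest organic component of a salt/mixture, rejecting records
   whose main component is ambiguous (distinct components of equal heavy-atom
   count);
2. neutralize charges where chemically valid;
3. canonicalize the tautomer with RDKit's deterministic MolVS-derived rules;
4. strip stereochemistry (so enantiomer records with discordant labels
   collapse into a detectable conflict);
5. emit the canonical SMILES.

Duplicate canonical structures are merged; structures whose pooled records
disagree in the binary label are removed entirely. All removals are tallied
in a :class:`CurationLog` satisfying an exact conservation identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

from rdkit import Chem, rdBase
from rdkit.Chem.MolStandardize import rdMolStandardize

__all__ = [
    "SENSITIZER",
    "NON_SENSITIZER",
    "DEFAULT_LABEL_VOCABULARY",
    "RawRecord",
    "CuratedRecord",
    "CurationLog",
    "InvalidStructureError",
    "SaltAmbiguityError",
    "LabelVocabularyError",
    "standardize_molecule",
    "map_label",
    "deduplicate_and_merge",
    "curate",
]

SENSITIZER = "sensitizer"
NON_SENSITIZER = "non_sensitizer"

#: Default raw-label vocabulary: LLNA potency classes collapse onto the binary
#: endpoint (any non-negative potency is a sensitizer).
DEFAULT_LABEL_VOCABULARY: Mapping[str, str] = {
    "negative": NON_SENSITIZER,
    "non-sensitizer": NON_SENSITIZER,
    "non_sensitizer": NON_SENSITIZER,
    "nonsensitizer": NON_SENSITIZER,
    "weak": SENSITIZER,
    "moderate": SENSITIZER,
    "strong": SENSITIZER,
    "extreme": SENSITIZER,
    "sensitizer": SENSITIZER,
}


class InvalidStructureError(ValueError):
    """The input SMILES could not be parsed into a molecule."""


class SaltAmbiguityError(ValueError):
    """The main component of a multi-component record is ambiguous."""


class LabelVocabularyError(KeyError):
    """A raw label is not covered by the supplied vocabulary."""


@dataclass(frozen=True)
class RawRecord:
    record_id: str
    structure: str
    label: str
    source: str = "unknown"


@dataclass(frozen=True)
class CuratedRecord:
    canonical_structure: str
    label: str
    provenance: tuple = ()  # tuple of (source, record_id)


@dataclass
class CurationLog:
    n_input: int = 0
    n_salt_ambiguous: int = 0
    n_invalid: int = 0
    n_duplicates_removed: int = 0
    n_conflicts_removed: int = 0
    n_output: int = 0
    tautomer_rules: str = ""

    def check_conservation(self) -> bool:
        return self.n_output == (
            self.n_input
            - self.n_salt_ambiguous
            - self.n_invalid
            - self.n_duplicates_removed
            - self.n_conflicts_removed
        )

    def to_dict(self) -> dict:
        return asdict(self)


# Standardizer components are expensive to construct; build once per process.
_UNCHARGER = None
_TAUTOMERIZER = None


def _uncharger() -> rdMolStandardize.Uncharger:
    global _UNCHARGER
    if _UNCHARGER is None:
        _UNCHARGER = rdMolStandardize.Uncharger()
    return _UNCHARGER


def _tautomerizer() -> rdMolStandardize.TautomerEnumerator:
    global _TAUTOMERIZER
    if _TAUTOMERIZER is None:
        _TAUTOMERIZER = rdMolStandardize.TautomerEnumerator()
    return _TAUTOMERIZER


def tautomer_rules_version() -> str:
    """Identifier of the deterministic tautomer rule set (for the log)."""
    return f"rdkit-molvs-{rdBase.rdkitVersion}"


def _largest_organic_component(mol: Chem.Mol, structure: str) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return frags[0]
    organic = [f for f in frags if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
    candidates = organic if organic else list(frags)
    sizes = [f.GetNumHeavyAtoms() for f in candidates]
    best = max(sizes)
    top = [f for f, s in zip(candidates, sizes) if s == best]
    if len(top) > 1:
        smis = {Chem.MolToSmiles(f) for f in top}
        if len(smis) > 1:
            raise SaltAmbiguityError(
                f"main component ambiguous in {structure!r}: {sorted(smis)}"
            )
    return top[0]


def standardize_molecule(structure: str) -> str:
    """Return the canonical standardized SMILES for one input structure.

    Idempotent: applying the standardizer to its own output is a no-op.

    Raises
    ------
    InvalidStructureError
        If the SMILES cannot be parsed.
    SaltAmbiguityError
        If non-identical components tie for largest organic component.
    """
    if not structure or not structure.strip():
        raise InvalidStructureError("empty structure")
    with rdBase.BlockLogs():
        mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise InvalidStructureError(f"unparseable SMILES: {structure!r}")
    mol = _largest_organic_component(mol, structure)
    mol = _uncharger().uncharge(mol)
    mol = _tautomerizer().Canonicalize(mol)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def map_label(raw_label: str, vocabulary: Mapping[str, str] | None = None) -> str:
    """Map a source-vocabulary activity label onto the binary endpoint."""
    vocab = DEFAULT_LABEL_VOCABULARY if vocabulary is None else vocabulary
    key = raw_label.strip().lower()
    if key not in vocab:
        raise LabelVocabularyError(f"label {raw_label!r} not in vocabulary")
    return vocab[key]


def deduplicate_and_merge(
    records: Iterable[RawRecord],
) -> tuple[list[CuratedRecord], CurationLog]:
    """Merge standardized, label-mapped records into unique curated records.

    Every record's ``structure`` must already be canonical (a fixed point of
    :func:`standardize_molecule`) and its ``label`` binary. One curated record
    is produced per canonical structure; structures whose pooled records carry
    both binary labels are dropped entirely and counted once each in
    ``n_conflicts_removed``. Duplicate counting follows the records-minus-
    unique-structures convention, which makes the log's conservation identity
    exact.
    """
    records = list(records)
    groups: dict[str, list[RawRecord]] = {}
    for rec in records:
        groups.setdefault(rec.structure, []).append(rec)

    curated: list[CuratedRecord] = []
    n_conflicts = 0
    for smi in sorted(groups):
        grp = groups[smi]
        labels = {r.label for r in grp}
        if len(labels) > 1:
            n_conflicts += 1
            continue
        prov = tuple(sorted((r.source, r.record_id) for r in grp))
        curated.append(CuratedRecord(smi, grp[0].label, prov))

    log = CurationLog(
        n_input=len(records),
        n_duplicates_removed=len(records) - len(groups),
        n_conflicts_removed=n_conflicts,
        n_output=len(curated),
        tautomer_rules=tautomer_rules_version(),
    )
    assert log.check_conservation()
    return curated, log


def curate(
    record_sets: Sequence[Iterable[RawRecord]] | Iterable[RawRecord],
    vocabulary: Mapping[str, str] | None = None,
) -> tuple[list[CuratedRecord], CurationLog]:
    """Full curation pipeline: standardize, map labels, deduplicate, merge.

    ``record_sets`` may be a flat iterable of :class:`RawRecord` or a sequence
    of per-source record collections; sources are pooled before deduplication.
    Unparseable structures and ambiguous salts are logged, not raised.
    """
    flat: list[RawRecord] = []
    record_sets = list(record_sets)
    if record_sets and isinstance(record_sets[0], RawRecord):
        flat = list(record_sets)  # type: ignore[arg-type]
    else:
        for rs in record_sets:
            flat.extend(rs)

    n_invalid = 0
    n_ambiguous = 0
    standardized: list[RawRecord] = []
    for rec in flat:
        try:
            canonical = standardize_molecule(rec.structure)
        except SaltAmbiguityError:
            n_ambiguous += 1
            continue
        except InvalidStructureError:
            n_invalid += 1
            continue
        standardized.append(
            RawRecord(rec.record_id, canonical, map_label(rec.label, vocabulary), rec.source)
        )

    curated, log = deduplicate_and_merge(standardized)
    log.n_input = len(flat)
    log.n_invalid = n_invalid
    log.n_salt_ambiguous = n_ambiguous
    assert log.check_conservation()
    return curated, log
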