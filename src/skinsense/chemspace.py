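"""Chemical-space characterization: PCA of interpretable descriptors, Murcko
scaffold census, and within-/cross-set Tanimoto similarity profiles.

Similarity profiles default to Morgan2/2048 fingerprints (where homologous
long-chain compounds can collapse onto identical bit vectors), while the
neighbor-based reliability machinery elsewhere defaults to MACCS keys — two
deliberately distinct defaults, both configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .curation import InvalidStructureError
from .features import DescriptorConfig, FeatureSet, compute_maccs, compute_morgan
from .reliability import tanimoto_similarities

__all__ = [
    "PCAModel",
    "ScaffoldSummary",
    "SimilarityProfile",
    "fit_pca",
    "project",
    "murcko_scaffold",
    "scaffold_census",
    "similarity_profile",
]


@dataclass
class PCAModel:
    loadings: np.ndarray  # (n_components, n_features), orthonormal rows
    explained_variance_fractions: np.ndarray  # non-increasing
    means: np.ndarray
    sds: np.ndarray


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, FeatureSet):
        return features.matrix
    return np.asarray(features, dtype=float)


def fit_pca(features, n_components: int, scale: bool = True) -> PCAModel:
    """Fit a PCA on (optionally standardized) continuous descriptors."""
    x = _as_matrix(features)
    if n_components > x.shape[1]:
        raise ValueError("n_components exceeds the number of features")
    means = x.mean(axis=0)
    if scale:
        sds = x.std(axis=0, ddof=0)
        sds[sds == 0.0] = 1.0
    else:
        sds = np.ones(x.shape[1])
    z = (x - means) / sds
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(z)
    return PCAModel(
        loadings=pca.components_,
        explained_variance_fractions=pca.explained_variance_ratio_,
        means=means,
        sds=sds,
    )


def project(model: PCAModel, features) -> np.ndarray:
    """Project (standardize, center, rotate) data into PCA score space."""
    x = _as_matrix(features)
    z = (x - model.means) / model.sds
    return z @ model.loadings.T


def murcko_scaffold(structure: str) -> str | None:
    """Canonical Murcko scaffold SMILES; None for acyclic molecules."""
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise InvalidStructureError(f"unparseable SMILES: {structure!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return None
    return Chem.MolToSmiles(scaffold)


@dataclass
class ScaffoldSummary:
    n_molecules: int
    n_scaffolds: int
    fraction_without_scaffold: float
    fraction_singleton_scaffolds: float
    top_scaffolds: list  # (scaffold SMILES, count), descending


def scaffold_census(structures: Sequence[str], top_n: int = 10) -> ScaffoldSummary:
    """Murcko scaffold diversity census of a compound set.

    The singleton fraction is the share of distinct scaffolds represented by
    exactly one molecule.
    """
    counts: dict[str, int] = {}
    n_without = 0
    for smi in structures:
        sc = murcko_scaffold(smi)
        if sc is None:
            n_without += 1
        else:
            counts[sc] = counts.get(sc, 0) + 1
    n = len(list(structures))
    n_scaffolds = len(counts)
    singletons = sum(1 for c in counts.values() if c == 1)
    top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    return ScaffoldSummary(
        n_molecules=n,
        n_scaffolds=n_scaffolds,
        fraction_without_scaffold=n_without / n if n else 0.0,
        fraction_singleton_scaffolds=singletons / n_scaffolds if n_scaffolds else 0.0,
        top_scaffolds=top,
    )


@dataclass
class SimilarityProfile:
    mode: str  # "within" | "cross"
    values: np.ndarray  # pairwise values (within) or per-query max (cross)
    quantiles: dict
    fraction_ge_threshold: float
    threshold: float
    n_identical_pairs: int  # pairs (or queries) with identical fingerprints
    sampled: bool = False


def _fingerprints(structures: Sequence[str], kind: str) -> np.ndarray:
    config = DescriptorConfig()
    if kind == "morgan2":
        return np.vstack([compute_morgan(s, config) for s in structures])
    if kind == "maccs":
        return np.vstack([compute_maccs(s) for s in structures])
    raise ValueError(f"unknown fingerprint kind {kind!r}")


def similarity_profile(
    query_set: Sequence[str],
    reference_set: Sequence[str] | None = None,
    fingerprint_kind: str = "morgan2",
    threshold: float = 0.6,
    max_molecules_exact: int = 5000,
    max_pairs: int = 2_000_000,
    seed: int = 43,
) -> SimilarityProfile:
    """Tanimoto similarity profile of a compound set.

    Cross-set mode (``reference_set`` given): for each query molecule, the
    maximum similarity to any reference molecule — a nearest-neighbor
    coverage profile. Within-set mode: the distribution of all n(n-1)/2
    pairwise similarities; for sets larger than ``max_molecules_exact`` a
    seeded uniform sample of ``max_pairs`` pairs bounds the cost.
    """
    query_set = list(query_set)
    if not query_set:
        raise ValueError("query set is empty")
    qfps = _fingerprints(query_set, fingerprint_kind)

    sampled = False
    if reference_set is not None:
        reference_set = list(reference_set)
        if not reference_set:
            raise ValueError("reference set is empty")
        rfps = _fingerprints(reference_set, fingerprint_kind)
        values = np.empty(len(qfps))
        n_identical = 0
        for i, q in enumerate(qfps):
            sims = tanimoto_similarities(q, rfps)
            values[i] = sims.max()
            if np.any((rfps == q).all(axis=1)):
                n_identical += 1
        mode = "cross"
    else:
        n = len(qfps)
        if n < 2:
            raise ValueError("within-set profile needs at least 2 molecules")
        if n > max_molecules_exact:
            rng = np.random.default_rng(seed)
            ii = rng.integers(0, n, size=max_pairs)
            jj = rng.integers(0, n - 1, size=max_pairs)
            jj = np.where(jj >= ii, jj + 1, jj)  # j != i, uniform over pairs
            pairs = list(zip(ii.tolist(), jj.tolist()))
            sampled = True
        else:
            pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        values = np.empty(len(pairs))
        n_identical = 0
        for idx, (i, j) in enumerate(pairs):
            inter = np.logical_and(qfps[i], qfps[j]).sum()
            union = np.logical_or(qfps[i], qfps[j]).sum()
            values[idx] = inter / union if union else 0.0
            if (qfps[i] == qfps[j]).all():
                n_identical += 1
        mode = "within"

    qs = {q: float(np.quantile(values, q)) for q in (0.25, 0.5, 0.75, 0.9)}
    return SimilarityProfile(
        mode=mode,
        values=values,
        quantiles=qs,
        fraction_ge_threshold=float(np.mean(values >= threshold)),
        threshold=threshold,
        n_identical_pairs=n_identical,
        sampled=sampled,
    )


def plot_pca_scores(scores: np.ndarray, groups=None, ax=None, **kwargs):
    """Scatter plot of PCA scores, optionally colored by group label."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if groups is None:
        ax.scatter(scores[:, 0], scores[:, 1], s=8, **kwargs)
    else:
        groups = np.asarray(groups)
        for g in np.unique(groups):
            m = groups == g
            ax.scatter(scores[m, 0], scores[m, 1], s=8, label=str(g), **kwargs)
        ax.legend()
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    return ax


def plot_similarity_profile(profile: SimilarityProfile, ax=None, bins=20):
    """Histogram of a similarity profile's values."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.hist(profile.values, bins=bins, range=(0, 1))
    ax.axvline(profile.threshold, color="k", linestyle="--")
    ax.set_xlabel("Tanimoto coefficient")
    ax.set_ylabel("count")
    return ax
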