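import numpy as np
import pytest

from skinsense import (
    SyntheticFeatureSpec,
    SyntheticMoleculeSpec,
    generate_features,
    generate_molecules,
)


@pytest.fixture(scope="session")
def clean_molecule_records():
    """Synthetic molecule set with no injected anomalies (seed 43)."""
    records, manifest = generate_molecules(SyntheticMoleculeSpec(seed=43))
    return records, manifest


@pytest.fixture(scope="session")
def messy_molecule_records():
    """Synthetic molecule set with salts, duplicates, conflicts, ambiguous
    salts and invalid structures injected at known rates."""
    spec = SyntheticMoleculeSpec(
        salt_fraction=0.1,
        duplicate_fraction=0.06,
        conflict_fraction=0.04,
        n_ambiguous_salts=4,
        n_invalid=3,
        seed=43,
    )
    return generate_molecules(spec)


@pytest.fixture(scope="session")
def feature_world():
    """Clustered feature-space world with distance-dependent label noise."""
    return generate_features(SyntheticFeatureSpec(seed=7))


@pytest.fixture(scope="session")
def separable_features():
    """Noise-free, well-separated feature world (labels fully learnable)."""
    spec = SyntheticFeatureSpec(
        n_train=240,
        n_test=120,
        far_fraction=0.0,
        flip_base=0.0,
        flip_slope=0.0,
        seed=11,
    )
    return generate_features(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
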