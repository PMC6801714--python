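"""Fingerprints, descriptors, the alert fingerprint and feature algebra."""

import numpy as np
import pytest

from skinsense.features import (
    PHYSCHEM_53,
    AlertConfigError,
    AlertLibrary,
    DescriptorConfig,
    FeatureSet,
    FeaturizationError,
    SchemaError,
    apply_scaler,
    build_feature_set,
    compute_alert_fingerprint,
    compute_maccs,
    compute_morgan,
    compute_physchem,
    concatenate_features,
    fit_scaler,
    invert_scaler,
)

BENZENE = "c1ccccc1"


class TestMaccs:
    def test_length_is_166(self):
        assert compute_maccs("C").shape == (166,)

    def test_benzene_aromatic_key_set(self):
        # published MACCS key 162 is "aromatic"; after dropping unused slot 0
        # it sits at index 161
        fp = compute_maccs(BENZENE)
        assert fp[161] == 1

    def test_methane_near_empty(self):
        assert compute_maccs("C").sum() <= 2

    def test_determinism(self):
        assert np.array_equal(compute_maccs("CCO"), compute_maccs("CCO"))

    def test_unparseable_raises(self):
        with pytest.raises(FeaturizationError):
            compute_maccs("C(")


class TestMorgan:
    def test_homologs_can_collapse(self):
        # identical halogen substitution, different chain length: radius-2
        # environments coincide, so the hashed fingerprints are identical
        a = compute_morgan("C" * 12 + "Cl")
        b = compute_morgan("C" * 14 + "Cl")
        assert np.array_equal(a, b)

    def test_methane_differs_from_ethane(self):
        assert not np.array_equal(compute_morgan("C"), compute_morgan("CC"))

    def test_nbits_contract(self):
        cfg = DescriptorConfig(morgan_nbits=512)
        assert compute_morgan("CCO", cfg).shape == (512,)

    def test_nbits_must_be_power_of_two(self):
        with pytest.raises(ValueError):
            DescriptorConfig(morgan_nbits=100)


class TestPhyschem:
    def test_has_53_descriptors(self):
        assert len(PHYSCHEM_53) == 53
        assert compute_physchem(BENZENE).shape == (53,)

    def test_benzene_molecular_weight(self):
        # atomic-mass oracle: 6 x 12.011 + 6 x 1.008 = 78.114
        vals = dict(zip(PHYSCHEM_53, compute_physchem(BENZENE)))
        assert vals["MolWt"] == pytest.approx(6 * 12.011 + 6 * 1.008, abs=0.01)

    def test_benzene_tpsa_zero(self):
        vals = dict(zip(PHYSCHEM_53, compute_physchem(BENZENE)))
        assert vals["TPSA"] == 0.0

    def test_molecular_weight_monotone_in_chain_length(self):
        i = PHYSCHEM_53.index("MolWt")
        assert compute_physchem("CCCCCC")[i] > compute_physchem("CCCCC")[i]


class TestAlertFingerprint:
    @pytest.mark.parametrize(
        "smiles, domain",
        [
            ("CC(=O)C=C", "michael_addition"),  # methyl vinyl ketone
            ("O=CCCCC=O", "schiff_base_formation"),  # glutaraldehyde
            ("CCCBr", "sn2_reaction"),
            ("CC(=O)Cl", "acylation"),
            ("O=C1C=CC(=O)C=C1", "nucleophilic_addition"),  # p-benzoquinone
        ],
    )
    def test_domain_bits(self, smiles, domain):
        lib = AlertLibrary.default()
        fp = compute_alert_fingerprint(smiles, lib)
        assert fp[lib.domain_names.index(domain)] == 1

    def test_ethane_has_no_alerts(self):
        assert compute_alert_fingerprint("CC").sum() == 0

    def test_five_domains_in_fixed_order(self):
        lib = AlertLibrary.default()
        assert lib.domain_names == [
            "michael_addition",
            "sn2_reaction",
            "schiff_base_formation",
            "acylation",
            "nucleophilic_addition",
        ]

    def test_invalid_smarts_raises_at_load(self):
        with pytest.raises(AlertConfigError):
            AlertLibrary([("bad", ["[C"])])

    def test_adding_pattern_is_superset_monotone(self):
        base = AlertLibrary([("michael_addition", ["[CX3]=[CX3][CX3]=[OX1]"])])
        wider = AlertLibrary(
            [("michael_addition", ["[CX3]=[CX3][CX3]=[OX1]", "[CX3]=[CX3][CX2]#[NX1]"])]
        )
        for smi in ("CC(=O)C=C", "C=CC#N", "CCO", "O=C1C=CC(=O)C=C1"):
            assert compute_alert_fingerprint(smi, wider) >= compute_alert_fingerprint(smi, base)

    def test_yaml_round_trip(self, tmp_path):
        lib = AlertLibrary.default()
        path = tmp_path / "alerts.yaml"
        lib.to_yaml(path)
        again = AlertLibrary.from_yaml(path)
        assert again.domains == lib.domains


class TestScaler:
    def _fs(self, matrix, kinds=None):
        matrix = np.asarray(matrix, dtype=float)
        kinds = kinds or ["continuous"] * matrix.shape[1]
        return FeatureSet(
            names=[f"f{i}" for i in range(matrix.shape[1])],
            matrix=matrix,
            kinds=kinds,
            molecule_ids=[str(i) for i in range(matrix.shape[0])],
        )

    def test_zero_two_column_scales_to_plus_minus_one(self):
        fs = self._fs([[0.0], [2.0]])
        scaled = apply_scaler(fs, fit_scaler(fs))
        assert np.allclose(scaled.matrix.ravel(), [-1.0, 1.0])

    def test_constant_column_scales_to_zeros(self):
        fs = self._fs([[5.0], [5.0], [5.0]])
        scaled = apply_scaler(fs, fit_scaler(fs))
        assert np.allclose(scaled.matrix, 0.0)

    def test_training_moments_after_scaling(self, rng):
        fs = self._fs(rng.normal(3.0, 2.5, size=(50, 4)))
        scaled = apply_scaler(fs, fit_scaler(fs))
        assert np.all(np.abs(scaled.matrix.mean(axis=0)) < 1e-8)
        assert np.all(np.abs(scaled.matrix.std(axis=0) - 1.0) < 1e-8)

    def test_binary_features_pass_through(self, rng):
        mat = np.hstack([rng.integers(0, 2, (20, 3)), rng.normal(size=(20, 2))])
        fs = self._fs(mat, kinds=["binary"] * 3 + ["continuous"] * 2)
        scaled = apply_scaler(fs, fit_scaler(fs))
        assert np.array_equal(scaled.matrix[:, :3], mat[:, :3])

    def test_invertibility(self, rng):
        fs = self._fs(rng.normal(size=(30, 5)))
        params = fit_scaler(fs)
        back = invert_scaler(apply_scaler(fs, params), params)
        assert np.allclose(back.matrix, fs.matrix, atol=1e-10)

    def test_schema_mismatch_raises(self, rng):
        fs = self._fs(rng.normal(size=(10, 3)))
        params = fit_scaler(fs)
        other = self._fs(rng.normal(size=(10, 3)))
        other.names = ["x", "y", "z"]
        with pytest.raises(SchemaError):
            apply_scaler(other, params)


class TestFeatureSetAlgebra:
    def test_concatenate_feature_counts(self):
        ids = ["m1", "m2"]
        smis = ["CCO", "CC(=O)C=C"]
        phys, _ = build_feature_set(ids, smis, "physchem")
        alerts, _ = build_feature_set(ids, smis, "alerts")
        combined = concatenate_features(phys, alerts)
        assert combined.n_features == 53 + 5
        assert len(set(combined.names)) == 58

    def test_concatenate_with_empty_is_identity(self):
        fs, _ = build_feature_set(["a"], ["CCO"], "maccs")
        empty = FeatureSet([], np.empty((1, 0)), [], ["a"])
        assert concatenate_features(fs, empty) is fs

    def test_mismatched_ids_raise(self):
        a, _ = build_feature_set(["m1"], ["CCO"], "maccs")
        b, _ = build_feature_set(["m2"], ["CCO"], "alerts")
        with pytest.raises(SchemaError):
            concatenate_features(a, b)

    def test_failed_molecules_are_flagged_and_excluded(self):
        fs, failed = build_feature_set(["ok", "bad"], ["CCO", "C("], "maccs")
        assert failed == ["bad"]
        assert fs.molecule_ids == ["ok"]

    def test_determinism_across_calls(self, clean_molecule_records):
        records, _ = clean_molecule_records
        ids = [r.record_id for r in records[:20]]
        smis = [r.structure for r in records[:20]]
        fs1, _ = build_feature_set(ids, smis, "maccs")
        fs2, _ = build_feature_set(ids, smis, "maccs")
        assert np.array_equal(fs1.matrix, fs2.matrix)
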