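"""Compute fingerprints and the 5-bit mechanistic alert fingerprint.

Featurizes a handful of electrophiles and inert molecules and prints which
protein-binding domain each alert bit represents and which molecules set it.
"""

from skinsense import (
    AlertLibrary,
    build_feature_set,
    compute_alert_fingerprint,
    compute_maccs,
    concatenate_features,
)

molecules = {
    "methyl vinyl ketone": "CC(=O)C=C",
    "glutaraldehyde": "O=CCCCC=O",
    "1-bromohexane": "CCCCCCBr",
    "acetyl chloride": "CC(=O)Cl",
    "p-benzoquinone": "O=C1C=CC(=O)C=C1",
    "hexane": "CCCCCC",
    "toluene": "Cc1ccccc1",
}

library = AlertLibrary.default()
print("Alert domains (bit order):", library.domain_names)
print()
for name, smi in molecules.items():
    bits = compute_alert_fingerprint(smi, library)
    hit = [d for d, b in zip(library.domain_names, bits) if b]
    print(f"  {name:22s} {smi:20s} -> {bits.tolist()}  {hit or 'no alert'}")

print()
ids, smis = list(molecules), list(molecules.values())
maccs, _ = build_feature_set(ids, smis, "maccs")
alerts, _ = build_feature_set(ids, smis, "alerts", library=library)
combined = concatenate_features(maccs, alerts)
print(
    f"MACCS keys ({maccs.n_features} bits) + alert fingerprint "
    f"({alerts.n_features} bits) -> combined set with {combined.n_features} "
    "features per molecule."
)
print(
    "Each alert bit records whether ANY pattern of one electrophilic reaction\n"
    "domain matches — the mechanistic link between structure and the covalent\n"
    "protein binding that initiates skin sensitization."
)
print(f"MACCS bits set for toluene: {int(compute_maccs('Cc1ccccc1').sum())} of 166")
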