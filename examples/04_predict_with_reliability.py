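"""Predict new molecules with applicability-domain and reliability flags.

Trains a MACCS-based random forest on a curated synthetic set, then assesses
query molecules — including one far outside the training chemistry and one
unparseable structure — and writes the per-molecule reliability report.
"""

import numpy as np

from skinsense import SyntheticMoleculeSpec, curate, generate_molecules
from skinsense.features import build_feature_set
from skinsense.io import write_prediction_report
from skinsense.modeling import fit_model
from skinsense.reliability import ReliabilityConfig, assess_batch

records, _ = generate_molecules(SyntheticMoleculeSpec(seed=43))
curated, _ = curate(records)
ids = [f"m{i}" for i in range(len(curated))]
smis = [c.canonical_structure for c in curated]
labels = np.array([1 if c.label == "sensitizer" else 0 for c in curated])

maccs, _ = build_feature_set(ids, smis, "maccs")
model = fit_model(
    maccs.matrix, labels, "rf", {"n_estimators": 100, "max_features": "sqrt"},
    seed=43,
    reference_fps=maccs.matrix.astype(int), reference_labels=labels,
)

queries = {
    "pent-1-en-3-one": "C=CC(=O)CC",  # close to the training Michael acceptors
    "octanal": "CCCCCCCC=O",  # close to the training aldehydes
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",  # far from training chemistry
    "broken": "C(",  # unparseable
}

cfg = ReliabilityConfig()  # 5-NN MACCS Tanimoto, AD cutoff 0.5, RF margin 0.15
results = assess_batch(list(queries), list(queries.values()), model, cfg)

print(f"{'molecule':18s} {'class':6s} {'score':>5s} {'dist':>5s} "
      f"{'5NN sim':>7s} {'conc':>4s} {'in AD':>5s}  warnings")
for r in results:
    if r.featurization_failed:
        print(f"{r.molecule_id:18s} featurization failed")
        continue
    cls = "sens" if r.predicted_class == 1 else "non"
    print(f"{r.molecule_id:18s} {cls:6s} {r.score:5.2f} {r.threshold_distance:5.2f} "
          f"{r.mean_knn_similarity:7.2f} {r.concordant_neighbors:4d} "
          f"{str(r.in_domain):>5s}  {';'.join(sorted(r.warnings)) or '-'}")

from pathlib import Path

Path("scratch").mkdir(exist_ok=True)
write_prediction_report(results, "scratch/prediction_report.csv", model.threshold)
print()
print("dist = |score - decision threshold| (scores within 0.15 of the RF\n"
      "threshold carry a low_margin warning); 5NN sim = mean Tanimoto\n"
      "similarity to the 5 nearest training compounds in MACCS space (below\n"
      "0.5 the molecule is outside the applicability domain); conc = number\n"
      "of consecutive nearest neighbors sharing the predicted class (0 means\n"
      "the nearest neighbor disagrees -> nn_conflict warning).\n"
      "Report written to scratch/prediction_report.csv")
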