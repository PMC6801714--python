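# Methods

This note documents the models, conventions and numerical choices behind
`skinsense`, the assumptions they rest on, and what the synthetic-data tests
do and do not establish.

## Endpoint and problem setting

The modeled endpoint is the binary outcome of the murine local lymph node
assay (LLNA): *sensitizer* vs *non-sensitizer*. Skin sensitization is
initiated by covalent binding of an electrophilic molecule (or its
metabolite) to skin proteins, which motivates both the mechanistic alert
fingerprint and the expectation that structurally similar molecules behave
similarly — the premise of the nearest-neighbor reliability machinery.
Potency vocabularies ("weak" … "extreme") collapse onto the binary label:
anything non-negative is a sensitizer.

## Curation

Standardization applies, in order: largest-organic-component selection,
charge neutralization (RDKit `Uncharger`), tautomer canonicalization (RDKit's
deterministic MolVS-derived `TautomerEnumerator`; the rule-set version is
recorded in every curation log), stereochemistry stripping, canonical SMILES
emission. The composition is idempotent (property-tested), so curated
structures are fixed points of the standardizer.

Conventions:

- **Largest component** is chosen by heavy-atom count among carbon-containing
  fragments (all fragments if none contain carbon). An exact tie between
  non-identical fragments is a *salt ambiguity*: the record is rejected and
  counted, never guessed.
- **Stereo is stripped before deduplication**, so enantiomer records with
  discordant labels deliberately collapse into a detectable conflict.
- **Conflicts** (one canonical structure, both labels) remove the structure
  entirely; each conflicting structure counts once in `n_conflicts_removed`.
  Duplicates are counted as records minus unique structures. With these
  conventions the log identity
  `n_output = n_input − n_salt_ambiguous − n_invalid − n_duplicates_removed −
  n_conflicts_removed` holds exactly on every run, and is asserted on every
  run.

Out of scope: registration-grade standardization (isotopes pass through,
no inorganic support).

## Descriptors and fingerprints

- **MACCS keys**: RDKit emits a 167-slot vector with slot 0 unused; slot 0 is
  dropped so the feature length is the conventional 166.
- **Morgan2**: radius 2, folded to 2048 bits (power of two enforced).
- **Physchem set**: 53 interpretable RDKit descriptors (size/composition,
  H-bonding, logP/MR, TPSA, ring and aromaticity counts, connectivity chi and
  kappa shape indices, E-state extrema, Morgan-density, QED). This is an
  open analog of the interpretable 2D subsets of commercial engines; no
  numeric identity with MOE or PaDEL values is claimed. The set is
  configuration (`DescriptorConfig.physchem_set`), not a constant.
- **Alert fingerprint**: 5 bits, one per protein-binding reaction domain
  (Michael addition, SN2, Schiff base formation, acylation, nucleophilic
  addition). Bit *d* is 1 iff any SMARTS pattern of domain *d* matches. The
  library ships as YAML (`skinsense/data/alerts.yaml`), is validated at load
  time, and its domain order fixes the bit order. Patterns are a compact,
  editable open substitute for closed structural-alert profilers; a molecule
  may legitimately light several domains (e.g. quinones are both Michael
  acceptors and nucleophilic-addition electrophiles).
- **Scaling**: continuous features are standardized to zero mean / unit
  variance with parameters fitted on training data only; binary features pass
  through. Zero-variance columns use sd = 1 (scaled column ≡ 0), avoiding
  division by zero. Inside cross-validation the scaler is refit per fold on
  the fold's training portion to prevent leakage.
- Featurization failures exclude a molecule from the matrix but keep it in
  reports with an explicit failure flag.

## Models

Random forest and RBF-SVM (scikit-learn), both with `class_weight="balanced"`
and a fixed random state (default 43). Hyperparameter grids (defaults):
RF `n_estimators ∈ {10, 50, 100, 250, 500, 1000}`,
`max_features ∈ {sqrt, 0.2, 0.4, 0.6, 0.8, all}`;
SVM `C ∈ {0.01 … 1000}`, `gamma ∈ {1 … 1e-5}` (six values each). The search
is exhaustive under stratified 10-fold cross-validation scored by mean fold
MCC; ties go to the earlier grid point, deterministically.

Score conventions: the RF score is the **fraction of trees voting
sensitizer** (in [0, 1], default threshold 0.5) — not the tree-probability
average, which differs in general; the SVM score is the **uncalibrated
signed margin** (real line, default threshold 0). A margin is the natural
SVM scale here because reliability margins of ~1.25 would be meaningless for
a [0, 1] probability. `classify` uses strict `score > threshold`; a tie goes
to the negative class, fixed for reproducibility. No probability calibration
is performed.

The train/test split is stratified with test size `ceil(f·n)` and per-class
counts by largest-remainder allocation (each class's test share within one
compound of the global fraction). At the published data-set scale — 1416
compounds, 572/844 — this yields exactly 284 test compounds (115/169), which
the acceptance suite asserts.

## Performance measures

MCC, ACC, AUC, Se, Sp, PPV, NPV and CCR = (Se+Sp)/2. MCC returns 0 when any
denominator factor is 0 (standard convention). Ratios with an empty
denominator (e.g. PPV with no positive predictions) are NaN with an
`undefined` flag — not coerced to 0; PPV = 0 still arises naturally from
TP = 0 with FP > 0. AUC is the Mann–Whitney rank statistic with ties counted
half (both classes required). Tests verify MCC exhaustively against an
independent route (Pearson correlation of indicator vectors) and AUC against
`scipy.stats.mannwhitneyu`.

## Applicability domain and reliability indicators

Neighbor space is MACCS-Tanimoto by default **regardless of the model's own
feature set** (configurable); a negative-Euclidean-distance variant exists
behind `neighbor_metric="neg_euclidean"` but correlates poorly with
structural similarity and is not recommended.

- Tanimoto of two all-zero fingerprints is defined as 0: a featureless
  molecule is dissimilar to everything — conservative for AD purposes.
- Neighbor ranking is by descending similarity with ties broken by training
  index (stable, platform-independent).
- **In domain** ⇔ mean 5-NN similarity ≥ 0.5 (boundary inclusive); the
  `low_similarity` warning uses strict `< 0.5`. A stricter 0.75 cutoff is
  carried in the config for high-confidence stratification.
- `low_margin` ⇔ |score − threshold| < 0.15 (RF) / 0.5 (SVM).
- `nn_conflict` ⇔ 0 concordant neighbors (the nearest neighbor's class
  differs from the prediction).

These indicators are heuristics; no conformal-style validity guarantee is
claimed. `binned_performance` supports both disjoint bins and cumulative
"≥ x" strata for reporting performance as a function of each indicator;
empty bins are emitted with n = 0 and flagged undefined metrics.

## Synthetic data: what it emulates, what it does not

**Molecular generator.** Seven programmatic families — alkyl chains and
alkylbenzenes (non-sensitizers), plus one homolog series per alert domain
(vinyl ketones, alkyl bromides/epoxides, aldehydes, acid chlorides,
alkylquinones). Defaults give 25 members per family, so every domain clears
a >20-instances-per-domain training bar. Anomalies are injected at stated
rates with exact bookkeeping: benign carbon-free counterions (HCl, water,
sodium) whose parents the salt filter must recover; ambiguous-salt records
built from two non-identical organic fragments of equal heavy-atom count;
exact duplicates; opposite-label conflict records; unparseable structures.
The generator's manifest states the exact curation log the pipeline must
reproduce — curation is tested against construction-time ground truth, not
against itself.

**Feature-space generator.** Classes live in several compact Gaussian
clusters (centers ~ N(0, 2.5²·I), within-cluster sd 0.7, alternating class
per cluster) — an idealization of chemical series, where structural
neighbors share activity, which is what makes nearest-neighbor concordance
informative. A fraction (default 0.4) of test points is displaced from its
cluster by r ~ U(1, 6) along a random diagonal; observed test labels flip
with probability min(0.02 + 0.12·r, 0.5). Displacement therefore produces,
by construction, exactly the phenomena the reliability indicators are meant
to detect: low similarity to training data, unstable scores, discordant
neighbors, and noisier labels. `grid_fingerprints` (one-hot bin per
dimension, width 1, clipped to ±6) supplies sparse binary vectors whose
Tanimoto similarity decays from 1 to 0 with distance, standing in for
substructure keys.

A green enrichment test establishes that the indicators separate reliable
from unreliable predictions *in a world with genuine structure–activity
continuity and distance-dependent noise*. It does not establish
toxicological realism, nor performance on real LLNA data (external
downloads, out of scope), nor that the particular cutoffs (0.5/0.75
similarity, 0.15/0.5 margins) are optimal for any real data set.

## Numerical and design choices

- All randomness flows from one top-level seed, expanded per stage by name
  hashing (`io.stage_seed`, always < 2³¹).
- Cross-validation folds are stratified (avoids degenerate folds; an
  unstratifiable minority class raises immediately, naming the fold).
- Whether to scale once before CV or per fold was an open choice; per-fold
  refitting was chosen to exclude leakage, at negligible cost.
- `max_features` is implemented as the features-per-split rule its name
  denotes (values: sqrt / fraction / all).
- Chemical-space profile fingerprints default to Morgan2/2048 while the
  reliability neighbor space defaults to MACCS — two deliberately distinct
  defaults, both configurable.
- Within-set similarity profiles are exact up to 5000 molecules and switch
  to seeded uniform pair sampling above that to bound cost.
- Test suites use reduced hyperparameter grids (2×2 RF, 3×2 SVM) and 5 folds
  to stay inside CI time budgets; the full published grid and 10 folds are
  the package defaults.

## Known limitations

- The 53-descriptor set is an analog, not a replica, of any commercial
  descriptor panel; models trained on it are not numerically comparable to
  ones built with closed engines.
- The alert SMARTS library is compact and illustrative rather than
  exhaustive; it is configuration and should be extended for production use.
- No 3D or quantum-chemical descriptors; no metabolic activation modeling —
  pre-haptens and pro-haptens will be systematically misjudged by purely
  structural alerts.
- Reliability indicators are empirical stratifiers, not calibrated
  probabilities or validity guarantees.
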