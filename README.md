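# skinsense

Machine-learning models for predicting the **skin-sensitization potential**
of small organic molecules — the binary endpoint of the murine local lymph
node assay (LLNA) — with a robust **applicability domain** (AD) and
**per-prediction reliability indicators**.

Skin sensitizers cause allergic contact dermatitis by covalently binding
skin proteins (haptenation). QSAR models for this endpoint are used by risk
assessors in the cosmetics, pharma and agrochemical industries, for whom a
bare class label is not enough: they need to know *when to trust a
prediction*. That reliability machinery is the core of this package.

## What it computes

Given a training set of molecules with binary labels, the package:

1. **Curates** raw records: keeps the largest organic component (rejecting
   ambiguous salts), neutralizes charges, canonicalizes tautomers, strips
   stereochemistry, deduplicates on canonical SMILES, and removes structures
   with conflicting labels — with an exactly-conserving bookkeeping log.
2. **Featurizes**: MACCS keys (166 bits), Morgan2 fingerprints (2048 bits),
   53 interpretable physicochemical descriptors, and a **5-bit mechanistic
   alert fingerprint** whose bits mark substructure alerts for the five
   protein-binding reaction domains — Michael addition, S<sub>N</sub>2
   reaction, Schiff base formation, acylation and nucleophilic addition
   (shipped as editable SMARTS config).
3. **Models**: random forest or RBF-kernel SVM with balanced class weights,
   hyperparameters chosen by exhaustive grid search under stratified 10-fold
   cross-validation scored by the Matthews correlation coefficient (MCC).
   RF scores are tree-vote fractions (threshold 0.5); SVM scores are signed
   margins (threshold 0). A molecule is called a sensitizer iff
   score > threshold.
4. **Assesses reliability** of each prediction with three indicators:
   - *mean 5-NN similarity*: mean Tanimoto coefficient to the five nearest
     training compounds in MACCS space; the query is **in domain** iff this
     is ≥ 0.5 (warning `low_similarity` otherwise);
   - *threshold distance* |score − threshold|: warning `low_margin` below
     0.15 (RF) or 0.5 (SVM);
   - *concordant neighbors*: number of consecutive nearest training
     neighbors sharing the predicted class; warning `nn_conflict` when the
     nearest neighbor already disagrees.
5. **Audits chemical space**: PCA of the interpretable descriptors, Murcko
   scaffold census (scaffold-free and singleton fractions), and within-set /
   cross-set Tanimoto similarity profiles.
6. **Generates synthetic data** (`skinsense.synthetic`) with known ground
   truth: LLNA-style molecule sets spanning all five alert domains with
   injected salts/duplicates/conflicts, and clustered feature-space worlds
   with distance-dependent label noise, so every claim above is testable
   offline.

## Worked example

`python examples/04_predict_with_reliability.py` trains a MACCS random
forest on a curated synthetic set and assesses four queries:

```
molecule           class  score  dist 5NN sim conc in AD  warnings
pent-1-en-3-one    sens    1.00  0.50    0.76   76  True  -
octanal            sens    1.00  0.50    1.00   64  True  -
caffeine           sens    0.60  0.10    0.20   25 False  low_margin;low_similarity
broken             featurization failed
```

The two electrophiles close to the training chemistry are predicted
sensitizer with every tree agreeing (score 1.00, distance 0.50 from the 0.5
threshold) and are in domain. Caffeine is structurally remote from the
training set (mean 5-NN Tanimoto 0.20 < 0.5): it is flagged out of domain
and its borderline score (0.60, only 0.10 above threshold) additionally
triggers the low-margin warning — exactly the prediction a risk assessor
should not act on. Unparseable input is reported as a featurization failure
rather than a silent drop.

The other examples cover curation bookkeeping (`01`), the alert fingerprint
(`02`), grid-search training and held-out evaluation (`03`), and the
chemical-space audit (`05`).

## Acceptance script

`scripts/acceptance.py` re-runs the whole pipeline from scratch at a given
seed — synthetic generation, curation, featurization, stratified split,
grid-search CV, final fit, and the reliability-stratum analyses — printing a
summary and writing its JSON result to `--out`:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

```
src/skinsense/      curation, features (+ data/alerts.yaml), modeling,
                    metrics, reliability, chemspace, synthetic, io
examples/           one narrative script per capability
tests/              pytest suite incl. acceptance criteria
docs/methods.md     models, parameters, conventions, limitations
```
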