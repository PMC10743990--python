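# consensusvs

Ligand-based virtual screening with a consensus of fingerprint classifiers,
built for kinase-inhibitor discovery campaigns (the motivating target is the
serine/threonine kinase GSK3β, but nothing in the library is
target-specific).

The package is aimed at computational chemists who have a table of potency
measurements (IC50 or Ki) and a commercial screening library, and want a
reproducible path from raw bioactivity records to a short list of novel,
alert-free candidate inhibitors with atom-level explanations of every
prediction.

## The method

**Curation.** Raw records are standardized (largest fragment, charge
neutralization, canonical structure key), deduplicated, and replicate
potencies aggregated: with three or more measurements, values deviating more
than 25% from the replicate mean are discarded and the survivors averaged;
two measurements are averaged directly. Compounds are labeled

- *active* if potency ≤ 0.1 µM (pIC50 ≥ 7),
- *inactive* if potency ≥ 0.5 µM (pIC50 ≤ 6.3),

and everything strictly between is excluded, giving the two clean classes a
binary classifier needs.

**Models.** Seven molecular representations (Morgan radius-2/2048 bits,
RDKit, Layered and Pattern fingerprints at 2048 bits, 2D-pharmacophore
fingerprints, the 881-key PubChem-style substructure fingerprint, and 128
physicochemical descriptors) are combined with four algorithm families —
Random Forest, SVM (linear or Tanimoto kernel K(x,y) = |x∧y|/|x∨y|),
k-Nearest Neighbors, and a Multi-layer Perceptron — each tuned by 5-fold
cross-validated accuracy over fixed default grids, then validated by ten
stratified 70/30 Monte-Carlo splits and a y-randomization control.

**Consensus.** Every trained model emits a probability score PS ∈ [0, 1]
for the active class. A consensus of models averages the member PSs into a
consensus score CS; CS ≥ 0.5 predicts active. All member combinations
(2ⁿ − n − 1 subsets of size ≥ 2) can be enumerated and ranked on a test set.

**Screening funnel.** The selected consensus scores a standardized library;
compounds with CS ≥ 0.8 are retained, those with Tanimoto ≥ 0.40 to any
training compound are removed (novelty filter), survivors are clustered by
Butina sphere exclusion on RDKit fingerprints at similarity 0.70, the
highest-CS member of each cluster is selected, and PAINS substructure
alerts are annotated; alerted compounds are excluded from the final pick.

**Explanations.** Per-bit Shapley values are estimated with an antithetic
permutation scheme over the Morgan bits (exactly additive: base value plus
the bit scores telescopes to the model's PS), each on-bit is retro-mapped to
its generating atom environments, and atoms accumulate

    fw_a = Σ_features fc / (n_Atoms · n_occ)

averaged over the consensus members, then rendered as a shaded 2D depiction.

## Worked example

The synthetic fixture generator plants a benzofuran scaffold as the "true"
activity determinant, so the whole pipeline can be exercised — and its
behavior verified against known ground truth — without any downloads:

```bash
consensusvs synth --n-actives 120 --n-inactives 120 --n-library 200 --seed 11 --out fixtures
consensusvs curate fixtures/activity_table.csv --role train --out curated
# -> 240 compounds (120 active / 120 inactive), 23 records audited
consensusvs train curated/train_dataset.csv --algorithm KNN --no-grid --seed 1 --out knn.joblib
consensusvs train curated/train_dataset.csv --algorithm RF  --no-grid --seed 1 --out rf.joblib
consensusvs consensus knn.joblib rf.joblib curated/train_dataset.csv --out consensus.joblib
consensusvs screen consensus.joblib fixtures/library.smi curated/train_dataset.csv --out screening
```

The final command prints the funnel summary:

```json
{"library": 200, "cs_filter": 35, "novelty_filter": 15, "clusters": 4,
 "representatives": 4, "final_selection": 4, "library_rejected": 0}
```

Reading: of 200 library compounds, 35 scored CS ≥ 0.8, 15 of those were
structurally novel (maximum Tanimoto to training < 0.40), they grouped into
4 clusters, and all 4 cluster representatives were PAINS-free — every one a
planted-scaffold bearer embedded in a framework unseen during training.
`screening/hits.csv` holds the annotated hit table.

Atom-level explanation of any compound:

```bash
consensusvs explain consensus.joblib curated/train_dataset.csv "O=C(NCC)c1cc2ccccc2o1" --out explanation
```

writes `atom_weights.csv` and a shaded depiction `atom_weights.svg`; the
benzofuran atoms carry the dominant positive weights.

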