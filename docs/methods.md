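# Methods

This note documents the models and procedures implemented in `consensusvs`,
the parameter choices that matter, what the synthetic fixtures do and do not
emulate, and the numerical conventions used throughout.

## Curation model

An activity table is a list of per-measurement records
(compound id, SMILES, potency in declared units, potency type IC50 or Ki,
relation). Curation proceeds record-wise:

1. **Standardization** — RDKit parse, largest-fragment selection, charge
   neutralization where a neutral protonation state exists (quaternary
   nitrogens keep their charge), canonical SMILES. The deduplication key is
   the InChIKey of the standardized structure, which is robust to SMILES
   aliasing; on the rare structures InChI refuses, the canonical SMILES
   itself is the key. Unparseable or heavy-atom-free inputs become audit
   records, never batch failures.
2. **Replicate aggregation** — one value passes through; two are averaged;
   with three or more, every value deviating more than 25% from the mean of
   the *initial* replicate list is dropped in a single pass and the
   survivors averaged. The single-pass reading (rather than iterating to a
   fixed point) is the simplest consistent interpretation and is frozen
   here; deviations are computed on the µM scale, not on pIC50. If nothing
   survives the compound is discarded (audited).
3. **Labeling** — active at ≤ 0.1 µM, inactive at ≥ 0.5 µM, excluded in
   between. The inactive boundary is treated as *inclusive* (≥ 0.5 µM):
   the protocol's two descriptions of this boundary differ in whether 0.5
   itself is inactive, and the inclusive reading matches the stated
   pIC50 ≤ 6.3 equivalence within rounding. Flagged here because a compound
   at exactly 0.5 µM changes class under the other reading.
4. **Censored data** — only `relation = "="` measurements are aggregated;
   `>`/`<` records are audited with a "censored" reason. Qualified values
   carry no usable point estimate for threshold labeling.

Every dropped record appears in the audit log with a reason, so
`n_input = n_used + n_audited` holds exactly (the pipeline warns if its own
reconciliation ever fails).

## Representations

| kind        | length | definition |
|-------------|--------|------------|
| morgan      | 2048   | circular fingerprint, radius 2, hashed |
| rdkit       | 2048   | subgraph path fingerprint |
| layered     | 2048   | layered substructure fingerprint |
| pattern     | 2048   | generic-SMARTS pattern fingerprint |
| pharm2d     | 885    | 2D-pharmacophore pairs/triplets |
| pubchem     | 881    | substructure keys (in-package implementation) |
| descriptors | 128    | physicochemical/topological descriptors |

**Pharm2D.** Feature families are H-bond acceptor, H-bond donor, positive
ionizable, negative ionizable, and aromatic (RDKit's base feature
definitions with all other families skipped), combinations of 2–3 features,
and topological distance bins (0–2, 2–5, 5–8 bonds). The bin edges are not
dictated by the protocol; these conventional defaults are fixed so the
vector length (885 under this scheme) is stable across runs. Lengths are
probed from the signature factory, never hard-coded.

**PubChem-style keys.** Implemented in-package from the public key layout:
element counts (114 keys), ring counts by size/composition/saturation (148),
bonded atom pairs (64), any-bond atom neighborhoods (90), bond-order-specific
neighborhoods (44), linear chains (253), and ring-substitution patterns
(168), totalling exactly 881. Sections 3–7 are SMARTS; sections 1–2 are
computed from atom tables and SSSR ring perception (an approximation of the
ESSSR perception the original document describes — fused-system edge cases
may differ). Where the public document's individual SMARTS are ambiguous,
keys follow this package's documented generation rules; per-key unit tests
pin the unambiguous ones. Every key is a monotone substructure predicate,
which the tests exploit (adding a disconnected fragment can only switch
bits on).

**Descriptors.** A pinned manifest of 128 names: the non-fragment RDKit
descriptor set minus `Ipc` (whose unscaled values overflow on large
molecules), plus four fragment counts (`fr_NH2`, `fr_amide`, `fr_ether`,
`fr_halogen`). Pinning matters because "the toolkit's descriptors" is a
moving, version-dependent target. NaN/inf values (e.g. BCUT on exotic
atoms) are imputed to 0 with a warning to keep matrices finite for every
backend.

**Tanimoto.** |a∧b|/|a∨b| on binary vectors; two all-zero vectors are
defined identical (1.0), a zero versus a nonzero vector scores 0. The same
conventions apply to the SVM kernel matrix.

## Classifiers

scikit-learn backs all four families; the Tanimoto kernel, probability
conventions and selection loops are implemented here.

- **RF** — `max_features ∈ {sqrt, log2, all}`, `n_estimators ∈ {100, 500}`.
  PS is the forest's averaged per-tree active probability.
- **SVM** — `C ∈ {0.01, 0.1, 1, 10, 100}`, kernel linear or Tanimoto. The
  Tanimoto kernel is precomputed (it is positive semidefinite on binary
  data; the tests check the minimum eigenvalue ≥ −1e−8) and is refused on
  the descriptor representation. Margin outputs are converted to PS by
  internal cross-validated sigmoid (Platt) calibration, the standard way to
  give an SVM a calibrated probability.
- **KNN** — `n_neighbors ∈ 1..30`, uniform or distance weights. PS is the
  (weighted) fraction of active neighbors. The distance metric on raw bit
  vectors is Euclidean, which induces the same neighbor ordering as Hamming
  on binary data; Jaccard is available via the `metric` hyperparameter.
- **MLP** — hidden layers {(50,50,50), (50,100,50), (100,)}, solvers
  {lbfgs, adam, sgd}, activations {identity, logistic, tanh, relu},
  initial learning rates {1e−2 … 1e−5}. PS is the logistic output. The
  default iteration cap is 1000 with a fixed seed; non-convergence is
  logged, not fatal, and the cap is a spec-level hyperparameter
  (`max_iter`) so selection loops on large grids can run under a smaller,
  explicitly recorded budget.

Descriptor inputs are z-scored inside the model pipeline with statistics
fit on the training portion only; fingerprints are used raw. Scaling
matters for the scale-sensitive learners (SVM, KNN, MLP) on unbounded
descriptors and is harmless for RF.

PS ∈ [0,1] for every family, and a model's label output is *defined* as
PS ≥ 0.5, so thresholding is always consistent with the reported labels.

## Selection and validation

- **Grid search** — every grid point is scored by 5-fold stratified
  cross-validated accuracy; the argmax wins with ties broken by grid
  enumeration order (first wins), making selection fully deterministic.
- **Repeated-split validation** — ten stratified Monte-Carlo 70/30 splits;
  the "10 × 70/30" protocol is deliberately subsampling, not standard
  10-fold partitioning, because each repeat trains on an independent random
  70% sample.
- **Row-order invariance** — before any seeded split the dataset rows are
  put in a canonical order (sorted by structure key, which is unique within
  a dataset). Identical data in a different row order therefore produces
  identical folds, selections and metrics.
- **y-randomization** — per repeat, training labels are permuted with a
  seeded RNG, the model is refit with the selected hyperparameters, and
  accuracy is measured on a stratified held-out 70/30 split of the permuted
  data (one split per permutation by default, configurable). An informative
  model collapses to ≈ 0.5 on balanced data; the unpermuted control stays
  high.

## Consensus and funnel

CS is the arithmetic mean of member PSs; CS ≥ 0.5 calls active. All member
subsets of size ≥ 2 are enumerated (2ⁿ − n − 1 for n models) in
deterministic order; combination ranking uses accuracy with precision as
the tiebreak, mirroring the emphasis of a screening campaign where the
candidate budget is small. Members are refit on the full training set
before screening.

Funnel defaults: CS ≥ 0.8 retention; novelty filter removes hits with
maximum Morgan/2048 Tanimoto ≥ 0.40 to any training compound (the models'
own representation is the natural choice; the original protocol does not
name the fingerprint for this step); Butina sphere-exclusion clustering on
RDKit fingerprints at similarity 0.70 (distance 0.30) — deterministic and
seedless by construction — with the highest-CS cluster member selected and
CS ties going to the lexicographically smallest id; PAINS annotation from
the openly published A/B/C SMARTS families as shipped with RDKit
(480 entries). The original campaign screened with a proprietary tool for
this last step, so the open catalog is a documented approximation. Each
stage outputs a subset of its input and the stage counts reconcile exactly.

## Attribution

Per-bit Shapley values are estimated by a model-agnostic permutation walk:
features are revealed one at a time (background value → compound value) in
a random order and its reverse (antithetic pair), and the marginal change
in the model's mean output over the background set is credited to the
revealed feature. One antithetic pass is exact for models with up to
second-order interactions; `n_permutations` (default 10) fresh permutations
refine the estimate for deeper interactions. Features identical between
the compound and every background row receive an exact zero and are skipped
(this is also the main computational saving). The estimator is exactly
additive by telescoping: base value (mean background prediction) plus the
sum of bit scores equals the model's PS up to float summation, asserted at
1e−6.

The default background is 100 training compounds sampled stratified by
label with a fixed seed — large enough to stabilize the base value,
label-balanced so the base sits near the decision boundary.

Retro-mapping: each Morgan on-bit maps to its generating environments
(center atom plus every atom touched by a bond within the bit's radius —
the inclusive reading of "atoms in the feature"); hash collisions put
several environments under one bit, counted as n_occ. Atom weights
accumulate fc/(n_Atoms · n_occ) per environment membership, so each
environment distributes exactly fc/n_occ and per model
Σ_atoms fw_a = Σ_mapped-bits fc to 1e−9 (pure arithmetic, tested).
Off-bits can carry nonzero Shapley scores (turning a bit *off* can be
informative) but have no generating environment and are excluded from the
atom map and its conservation balance; an on-bit with a nonzero score that
is missing from the map triggers a warning. Final atom weights average the
member models' weights. Depictions shade atoms red (toward active) or blue
(toward inactive) proportional to |fw_a|, written as SVG (PNG via Cairo).

## Synthetic fixtures

The generator emulates a curated kinase-inhibition campaign with known
ground truth. Actives are benzofuran-2-carboxamide analogs: a planted
benzofuran scaffold (SMARTS `c1ccc2occc2c1`) decorated from a fixed
vocabulary of small alkyl/alkoxy/amino substituents and ring halogens.
Decoys come from scaffold-free template families — benzamides, pyridine
carboxamides, indole- and benzothiophene-2-carboxamides (deliberate
near-miss bicyclics), sulfonamides, piperazines — none matching the planted
SMARTS (asserted at generation). Potencies are log-normal
(active median 0.02 µM, σ_ln 0.6; inactive median 5 µM, σ_ln 0.8),
truncated to ≤ 0.095 µM / ≥ 0.51 µM so that aggregation noise can never
move a compound into the excluded band — curation therefore recovers the
planted class counts exactly, which the tests rely on. A configurable 10%
of compounds receive three replicates [v, 1.02v, 1.9v]; the 1.9v injection
deviates 45% from the replicate mean (> 25%, removed) while the other two
deviate ≤ 23.5% (kept), so the aggregation rule is exercised on every
generated table without perturbing labels by more than ~1%.

Screening libraries mix three families: *close* analogs (the active
templates decorated from a held-out vocabulary), *remote* analogs (the
benzofuran core embedded in frameworks unlike the training actives —
sulfonyl-piperazines, benzoyl-piperidines, benzothiazole biaryls — which
stay below 0.40 Morgan Tanimoto to every training compound and therefore
survive the novelty filter), and decoys. The training selection is
reproduced from the seed so no library compound is identical to a training
compound. With the default composition the funnel reproduces the
characteristic shape of a real campaign: the CS filter passes scaffold
bearers, the novelty filter eliminates the close analogs, and the final
selection is remote scaffold bearers.

What the fixtures do *not* emulate: a real SAR landscape (activity is a
pure substructure function with no activity cliffs), assay noise structure
beyond log-normal spread, chemical diversity at commercial-library scale,
or any target-specific binding physics. Passing tests therefore demonstrate
that the machinery is correct and well-calibrated on a planted signal, not
that any given real target will be this separable (the fixtures are close
to linearly separable in Morgan space; real campaigns are not).

## Problem sizes and determinism

The test suite runs at n = 240–400 compounds and 200-compound libraries;
`scripts/acceptance.py` uses the balanced n = 400 dataset, full default
grids for all four families (with a recorded 100-iteration training budget
for the MLP selection loop, which does not change the grid's 144
combinations), and 10 y-randomization repeats per family. All randomness
flows from explicit seeds (a single top-level seed fanned out per stage in
the CLI); repeated runs are byte-identical, and several tests assert this.

## Known limitations

- The PubChem-style fingerprint matches the public layout and semantics
  but is not bit-compatible with CACTVS output; use it as a consistent
  in-package representation, not for interoperability.
- SVM probability calibration (internal 5-fold Platt scaling) can be
  noisy below ~50 training compounds per class.
- Permutation attribution cost grows with background size × number of
  varying bits; KNN members dominate the cost because their prediction is
  the most expensive per row.
- The novelty filter compares Morgan/2048 fingerprints only; scaffold-level
  novelty (e.g. Murcko frameworks) is out of scope.
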