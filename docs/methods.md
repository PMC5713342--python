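# Methods

This note documents the models, conventions and numerical choices behind
`lctd`, including the points where the underlying descriptor definitions
are ambiguous and a convention had to be fixed.

## Reduced alphabet and descriptors

The 20 standard amino acids are collapsed into 7 classes by side-chain
dipole moment and volume ({A,G,V}, {C}, {F,I,L,P}, {M,S,T,Y}, {H,N,Q,W},
{K,R}, {D,E}). Sequences are upper-cased before validation; ambiguity
codes (B, J, O, U, X, Z) are rejected with the offending position rather
than skipped, because silently dropping residues would shift every region
boundary downstream. Descriptor computation requires length ≥ 8 (so all
10 regions are non-empty); the dataset builders additionally apply the
conventional ≥ 50-residue benchmark filter, as a separate, configurable
rule.

### Region scheme

For length L, quarter boundaries are b_k = floor(kL/4), k = 0..4.
Regions: quarters A–D, halves E = [b0, b2) and F = [b2, b4), central 50%
G = [b1, b3), first/final 75% H = [b0, b3) and I = [b1, b4), central 75%
J = [floor(L/8), floor(7L/8)). The floor convention is a choice — the
region scheme is conventionally drawn, not defined arithmetically, for
non-divisible lengths — and was picked because it is deterministic,
keeps A∪B∪C∪D and E∪F exact partitions for every L, and matches common
composition/transition/distribution implementations. "Central 75%" has no
standard arithmetic at all; [floor(L/8), floor(7L/8)) centres it up to
rounding.

### Block definitions and frozen orderings

* **Composition**: C_g = 100·count(g)/|region|, class order 0..6.
* **Transition**: for each unordered class pair {g,h}, g<h in
  lexicographic order (0,1),(0,2),…,(5,6): 100·(# adjacent positions
  switching between g and h in either direction)/(|region|−1); the zero
  vector for a length-1 region.
* **Distribution**: per class (class-major), the 1-based positions of the
  first occurrence and of the round-half-up(q·n)-th occurrence for
  q ∈ {0.25, 0.5, 0.75, 1.0} (clamped to ≥ 1), each divided by |region|,
  ×100; five zeros for an absent class. The round-half-up ordinal rule is
  the one consistent with the classic worked example's class-1 row
  (n = 7 → ordinals 1,2,4,5,7). Published accounts of the same example
  contain two internal inconsistencies (the class-0 distribution row
  divides ordinals rather than positions by the length, and two of the
  three printed transition values do not match the printed encoded
  string); this implementation treats them as errata and follows the
  definitions, which its tests verify by brute-force recounting.
* **Conjoint triads**: every window of three consecutive classes inside a
  region, indexed i = c₁ + 7c₂ + 49c₃ (first symbol least significant).
  Windows never span region boundaries: each region is treated as an
  independent subsequence. Normalisation follows the original recipe
  literally, d_i = (f_i − min_j f_j)/max_j f_j (divide by max, not
  max − min); an all-zero count vector maps to all zeros. A `min_max`
  switch provides standard min–max scaling as a documented variant,
  default off.
* **Scales**: C/T/D are percentages (0–100), triad values are in [0, 1].
  Pair vectors concatenate A's protein vector then B's, in the input
  orientation; no two-orientation augmentation is performed.

## Classifier

A fully-connected network: input (8120 for LCTD pairs) → 2048 → 512 → 32
→ 1. Hidden layers apply affine → batch normalisation → ReLU → dropout
(rate 0.6); the output is a single logistic unit and training minimises
mean binary cross-entropy (probabilities clipped to [1e−7, 1−1e−7]) with
Adam at learning rate 0.002 and batch size 512. Weights are initialised
with Glorot-normal. Defaults follow the configuration recommended for
this descriptor/classifier family; depth and widths are configurable.

Choices the family definition leaves open, fixed here:

* a single logistic output with threshold 0.5 (rather than a 2-way
  softmax);
* per-layer ordering affine → batch-norm → ReLU → dropout (the common
  convention);
* batch-norm running statistics with momentum 0.9, ε = 1e−5;
* epoch budget: default 100 with early stopping once the epoch-mean
  training loss stops improving by 1e−4 for 10 consecutive epochs;
* **input standardisation** (default on): features are z-scored by
  training-set mean and standard deviation, stored in the model and
  re-applied at inference. The descriptor vector mixes 0–100 percentage
  scales with 0–1 triad values; without equalisation the optimiser
  spends its capacity on the high-scale coordinates and the informative
  triad sub-blocks are effectively invisible at realistic training-set
  sizes.

All randomness — initialisation, shuffling, dropout masks — flows from a
single seed, and inference uses running batch-norm statistics with
dropout disabled, so predictions are deterministic and independent of how
rows are batched. The implementation is plain numpy; parameters and both
passes are explicit arrays, which keeps the model fully seedable and
dependency-light.

## Evaluation

ACC, precision, recall, specificity, MCC and F1 are computed from the
confusion table at threshold 0.5 (configurable); any metric with a zero
denominator is reported as missing, never as 0. AUC is the rank-based
(Mann–Whitney) statistic with ties counted ½, equivalent to the
trapezoidal area under the full-threshold ROC sweep. Cross-validation is
stratified by class (the datasets are balanced, so this mainly removes
fold-to-fold class jitter), with the fold assignment a pure function of
the seed; aggregates are the mean and sample (n−1) standard deviation
over folds, with a fold's AUC skipped (and logged) if the fold holds a
single class.

## Synthetic benchmark

The generator emulates the standard construction of a PPI benchmark:

* **Proteome**: n sequences with i.i.d. residues from a configurable
  background (default uniform over the 20 letters) and uniform lengths in
  [min, max]; each protein gets one of `n_localizations` subcellular
  compartment labels, uniformly.
* **Positives**: disjoint protein pairs (each protein in at most one
  interacting pair). With probability `motif_strength` a pair receives a
  compatible *interface motif pair*: two fixed class-patterns of
  `motif_length` residues (drawn once per dataset from the seed), written
  into a random window of partner A and partner B respectively, with each
  class realised by a uniformly chosen member residue. The signal
  therefore lives at the reduced-alphabet level and is visible to all
  three descriptor families.
* **Negatives**: uniform over cross-localization protein pairs, excluding
  (i) pairs present in the positive set and (ii) pairs that combine an
  A-motif carrier with a B-motif carrier — by the generator's own model
  such proteins interact, so labelling them negative would be a
  construction-level false negative.

Default study conditions: 1,000 positives + 1,000 negatives (balanced,
as in curated benchmarks), motif length 6, motif strength 0.9, drawn from
a 40,000-protein proteome with lengths 50–100 and 4 compartments. The
proteome is deliberately much larger than the pair list and the sequences
short: motif carriers then stay rare among negatives (~4% per slot) and
the per-region triad background is sparse, which keeps the implanted
signal statistically recoverable from a 2,000-pair training set. At these
settings the ceiling on achievable AUC is ≈ 0.95 (10% of positives carry
no motif), a direct motif-counting oracle reaches ≈ 0.95, and LCTD +
the default network reaches ≈ 0.93–0.94 mean AUC in five-fold CV; with
motif strength 0 the same pipeline stays at chance (AUC ≈ 0.5), confirming
the pipeline manufactures no spurious signal.

What the generator does *not* emulate: real interface biophysics,
homology/redundancy structure (no identity filtering is performed),
length–function correlations, compositional biases, or annotation noise.
Passing the end-to-end checks therefore shows that the pipeline can
recover a planted sequence-level pairing signal at realistic noise levels
— not that it attains any particular accuracy on curated interaction
data.

## Problem sizes used in tests and the acceptance script

The end-to-end runs use the default 2,000-pair benchmark with five-fold
CV and the default architecture/optimiser at epochs = 25, patience = 5 —
the saturation point of this task (doubling the epoch budget changes mean
AUC by < 0.001, as the network reaches training AUC 1.0 long before).

## Known limitations

* Eq-as-printed triad normalisation (divide by max) is kept for fidelity;
  it maps the *least* frequent triad to a non-zero value whenever
  min > 0, unlike true min–max scaling (available via `min_max=True`).
* The descriptor is orientation-sensitive: (A, B) and (B, A) produce
  different vectors. Real interaction lists have no canonical
  orientation; users may wish to augment both orientations.
* The numpy network targets desk-scale problems; it is single-threaded
  BLAS-bound and has no GPU path.
* The 40% sequence-identity redundancy filter used when curating real
  benchmarks is out of scope; apply external clustering before encoding
  if redundancy matters.
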