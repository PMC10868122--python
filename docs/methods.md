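# Methods

## Problem and sample formulation

The task is binary classification of RNA windows: does the central
adenosine of a fixed-length window carry the m1A modification?  A window
is an odd-length fragment (default W = 41, a length standard for
verified m1A flanks) over {A, C, G, U} with A forced at the center;
positives are labeled 1, negatives 0.  At prediction time an
arbitrary-length sequence is scanned per adenosine, and every A with
full ±(W−1)/2 flanks yields one window and one call.  Windows are
strand-agnostic (no reverse-complementation — the input is RNA), and
T on input is silently transcribed to U; any other non-ACGU symbol is
rejected rather than imputed.

## Feature encoding

Bases are coded A=1, C=2, G=3, U=4 — an arbitrary but frozen bijection
(alphabetical over the RNA alphabet).  Moment values depend on this
choice, so it is fixed package-wide.  Positions are 1-based everywhere.

Six groups concatenate to 522 values (sizes 90/90/84/84/84/90, order
PRIM, RPRIM, FV, AAPIV, RAAPIV, SEQMAT):

* **k-mer token streams.**  Overlapping windows of size k ∈ {1, 2, 3},
  stride 1, coded lexicographically with A < C < G < U (AA…A = 1).  The
  occurrence position of a di-/tri-nucleotide is the 1-based index of its
  first base.
* **PRIM (position-relative incidence matrix).**  A 4^k × 4^k matrix in
  which cell (i, j) accumulates the forward distance q − p over every
  ordered pair of stream positions p < q holding tokens i and j.  The
  precise accumulation rule is a design choice of this package: any fixed
  rule that preserves relative-position information would serve; the
  pairwise-distance sum is simple, order-sensitive (PRIM of a sequence
  and of its reversal differ) and directly testable by brute-force pair
  enumeration.  RPRIM is PRIM of the reversed (not complemented) symbol
  sequence.
* **FV (frequency vector).**  The 84 overlapping k-mer counts.
* **AAPIV / RAAPIV.**  Per k-mer, the sum of its 1-based occurrence start
  positions in the forward / reversed stream, giving 4 + 16 + 64 values
  each.  A useful invariant used in the tests: the mono-level entries of
  either vector always sum to W(W+1)/2.
* **SEQMAT.**  The token stream packed row-major into the smallest
  square matrix (side ⌈√count⌉), zero-padded at the tail.

### Statistical moments

Every matrix-valued group is reduced to 30 coefficients: raw, central and
Hahn moments at the ten orders (j, k) with j + k ≤ 3, in the frozen order
(0,0), (0,1), (1,0), (1,1), (0,2), (2,0), (1,2), (2,1), (0,3), (3,0).
Raw and central moments use 1-based matrix indices; central moments are
taken about the mass centroid, making them translation-related rather
than position-bound.  Hahn moments project the matrix onto discrete Hahn
polynomials h_n^{u,v}(r, N) evaluated from the hypergeometric sum with
rising-factorial Pochhammer symbols, over 0-based abscissas, in the
separable 2-D product form (one polynomial factor per axis — the only
form in which H_ij depends on both orders).  Numerical notes:

* The polynomials are used as printed, un-normalized (no ρ-weighting);
  coefficients at order ≤ 3 on matrices up to 64×64 stay well inside
  float64 range, so no log-domain evaluation is needed.
* The shape parameters default to u = v = 0 and are exposed through the
  API (`assemble(window, u, v)`); they tilt the polynomial weight toward
  one end of the support.
* For matrices smaller than 4×4 the order-3 polynomial lies outside its
  orthogonality range; the analytic sum remains well-defined and is used
  as-is (this matters only for toy matrices — the production matrices
  are 4×4 and larger).
* A token stream with fewer than two tokens yields an all-zero PRIM
  matrix, whose centroid is undefined; its 30 coefficients are taken as
  the zero limit.  This cannot occur at W = 41.

The moment engine is verified against naive double-loop summation and
exact rational (fractions-based) polynomial evaluation on random
matrices of sides 2–16, to 1e-9 relative tolerance.

## Classifiers

Nine configurations in three families, hyperparameters frozen in a
registry (`m1apred.ensembles.MODEL_REGISTRY`); unspecified settings take
library defaults.  All models consume column-standardized features
(scaler fit on the training partition only; constant columns pass
through) and expose calibrated-ish scores in [0, 1] thresholded at 0.5.

* **Blending** — base learners: MLP (hidden sizes 5, 2, relu, lbfgs,
  alpha 1e-4), 3-NN, RBF-SVC (C = 10, gamma = 1e-4, probability
  estimates on), decision tree (random splitter, depth ≤ 80, min leaf 4);
  meta-learner: gradient boosting with 100 estimators.  The stacking
  protocol uses an inner 80/20 split of the training partition: base
  learners fit on the inner 80%, their scores on the remaining 20% train
  the meta-learner, and the bases are then refit on the full partition
  for prediction.  Without the holdout the meta-learner would see the
  bases' training error, which is optimistically biased.  Note the MLP's
  adaptive learning-rate setting is inert under the lbfgs solver
  (scikit-learn only applies it to sgd); the registry records the
  combination as configured.
* **Bagging** — random forest (200 trees, depth ≤ 50, min split 10, min
  leaf 5), extra trees (100 trees, depth ≤ 40, bootstrapped), a single
  randomized decision tree, and an in-package bootstrap aggregator of
  decision trees (100 members, out-of-bag accuracy recorded).  The
  aggregator uses majority voting for labels with ties broken toward the
  negative class — a positive call needs a strict majority — and the
  member-score mean for probabilities.
* **Boosting** — gradient boosting (rate 0.1, 100 estimators),
  histogram-based gradient boosting (200 iterations, depth ≤ 40),
  AdaBoost (50 estimators, stump base learners), XGBoost (100 rounds,
  depth ≤ 40).

With a fixed seed the whole train→predict path is deterministic; the
seed feeds every stochastic component (splits, tree randomness,
bootstrap draws).

## Evaluation and comparison

Confusion-derived metrics follow the standard formulas (README); MCC
returns 0 when any factor under its root vanishes, and Sn/Sp return 0
for an empty class — degenerate tables then still yield finite reports.
AUROC is computed by the Mann–Whitney rank formulation with ties counted
half.  Protocols: a stratified 70/30 independent split (stratification
keeps class proportions within one sample per class; near-balanced
train/test class counts motivated the choice) and shuffled k-fold
cross-validation (default k = 10) reporting per-fold and mean metrics.

Model comparisons: pooled two-proportion z test (two-sided normal);
McNemar's test on the discordant counts b, c — exact binomial for
b + c < 25 (threshold configurable), else chi-square with the continuity
correction clamped at zero so b = c gives statistic 0 and p = 1; and the
resampled paired t-test — accuracy differences over repeated random
stratified 70/30 resplits, t with trials − 1 degrees of freedom, with a
zero-variance guard (t = 0, p = 1 for a zero mean; ±∞, p = 0 otherwise).
Accuracy is the paired statistic because the comparison targets overall
correctness of the calls.

## Synthetic data

The generator produces labeled windows with the qualitative structure of
real m1A window sets: U/A-rich background (per-position probabilities
A 0.35, G 0.25, U 0.40 away from the center), G spread evenly, and C
confined to the five positions centered on the candidate A (probability
0.20 inside the band, 0 outside), center forced to A.  The numeric
profile values are toolkit choices — real data constrain the pattern
only qualitatively — and are fully exposed in `GeneratorConfig`.

Class signal is a planted positional dinucleotide (default AG written
immediately 5′ of the center) applied to each positive with probability
min(1, effect/3).  Design rationale: a dinucleotide at a fixed position
loads the position-sensitive groups (PRIM, AAPIV), not just composition
counts, so end-to-end recovery genuinely exercises the positional
encoding; the linear ramp reaches certainty at the nominal strong
setting effect = 3, mirroring how genuine modification contexts (e.g.
the GUUCRA T-loop consensus around tRNA m1A58) accompany essentially
all modified sites, while effect = 0 makes the classes exactly
exchangeable.  At effect = 3 and n = 2000 the
histogram-gradient-boosting pipeline reaches held-out AUROC ≈ 0.92–0.95
(the residual gap to 1 comes from negatives that carry AG by chance,
~6% at the planted slot); at effect = 0 it sits at chance.

What the generator does **not** model: inter-position dependence beyond
the planted motif, species mixture, homology between windows, label
noise, or the class-size imbalance of real collections.  Passing the
end-to-end tests therefore demonstrates that the pipeline can recover a
planted positional signal of known strength — not any particular
accuracy on real m1A data.

## Problem sizes in the shipped tests

The test suite and the acceptance script run the recovery experiment at
n = 2000 windows and the nine-model sweep at n = 400, with 60–200 random
matrices in the moment-oracle sweeps — sizes chosen so the full suite
completes in a few minutes on one CPU while keeping the statistical
checks comfortably powered.

## Known limitations

* The PRIM accumulation rule and the base-integer mapping are frozen
  conventions; vectors encoded under different conventions are not
  comparable.
* Hahn moments are computed on un-normalized polynomials; orthonormal
  variants would change scale but not information content.
* Model bundles are serialized with joblib and are not portable across
  major scikit-learn versions.
* No feature selection, alternative encodings, or deep models are
  provided; the published nine configurations are the scope.
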