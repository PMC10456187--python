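# Methods

## Estimation model

The package treats an observer's mental representation of a target facial
expression as a binary activation pattern over a catalog of facial action
units, structured as one *dominant* AU plus a set of *complementary* AUs.
The structure is estimated purely from 2AFC choices; no parametric model
of the observer is fitted. The two stages are deliberately asymmetric:

* The dominant stage uses, per AU, every trial in which exactly one of the
  two stimuli bears that AU (Ω_{i*}). With the default design (16 AUs,
  3 active per stimulus) an AU appears in 3/16 of stimuli, so |Ω_{i*}| ≈
  2·(3/16)(13/16)·m ≈ 0.30·m — roughly 255 of 840 trials per AU. The
  dominant proportion is therefore a well-sampled statistic.
* The complementary stage conditions on the dominant AU being present in
  *both* stimuli (Ω_d), which keeps only ≈ (3/16)²·m ≈ 29 of 840 trials,
  and within those, each per-AU subset Ω_{d,j*} holds only ~7 trials.
  Complementary estimates are intrinsically small-sample; this is a
  property of the experimental design, not of the implementation.

Assumptions: choices are independent across trials; the question (target
expression) is fixed within an experiment; activation is binary — per-AU
intensity exists only as an export-time rendering parameter.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `au_ids` | 16 ids (1,2,4,5,6,7,9,10,12,14,15,17,20,23,25,26) | AU catalog; the default is the AU set an OpenFace-driven AU renderer can manipulate, overridable everywhere |
| `k_active` | 3 | AUs active per design stimulus (more creates rendering artifacts) |
| `m` | 840 | trials per experiment (~40–60 min for a human observer) |
| `T_q` (`threshold`) | 0.8 | complementary cutoff, dimensionless proportion; must sit well above 0.5 to select only informative AUs; 0.7 is a reasonable choice for subtler attributions such as self-confidence |
| `dominant_weight` / `complementary_weight` | 2.0 / 1.0 | simulated-observer score weights; any values with w_d > w_c > 0 encode "the dominant AU drives perception more than any single complementary AU" |
| `temperature` | 0.0 | logistic choice noise on the score difference (0 = hard argmax) |
| `lapse_rate` | 0.0 | probability of a uniformly random answer |

## Numerical and procedural choices

* **Ties in the dominant argmax** return the smallest AU id and emit a
  warning. Deterministic output was preferred over random tie-breaking.
* **Zero-denominator proportions are undefined**, flagged as such in
  proportion tables, and excluded from the argmax and from thresholding —
  fabricating 0 or 0.5 would bias both stages.
* **Thresholding is inclusive** (≥ T_q), so a proportion exactly at the
  cutoff counts as complementary.
* **Convergence curves** use the Pearson correlation between the partial
  and final per-AU proportion vectors, dropping undefined bins pairwise.
  Points with fewer than two commonly defined bins, or with a constant
  (zero-variance) partial histogram, are flagged undefined rather than
  given an arbitrary value. "First n trials" follows the chronological
  (file) order of the response log; for the complementary stage, the
  chronological subsequence of Ω_d.
* **Schedule sampling** draws unordered pairs uniformly without
  replacement by unranking uniform indices into the lexicographic pair
  order, then randomizes presentation side independently; everything is
  reproducible from a single integer seed.
* **Simulated-observer ties** (equal stimulus scores at temperature 0) are
  resolved by a seeded fair coin.
* **Schulze strengths** use the winning-votes link rule (a link i→j exists
  only when counts(i,j) > counts(j,i)) and Floyd–Warshall max–min
  relaxation. The final ranking counts wins in the beats-relation
  p(i,j) > p(j,i), which matches the Schulze order whenever the relation
  is total — true for all bundled published matrices. Exact strength ties
  share a rank position with a warning; a cyclic beats-relation is
  rejected as invalid input, since genuine strongest-path strengths cannot
  produce one. Published percentage matrices are accepted as strengths
  directly: the underlying raw ballots are not available, and the ranking
  derivation needs only the pairwise comparisons.

## What the simulated observer does and does not show

The observer model is a test fixture: a linear additive score
(w_d·[dominant active] + w_c·|C ∩ active|) with logistic/lapse noise. It
reproduces the *structural* dependency the estimator targets — the
dominant AU drives choices on its own, complementary AUs only in the
dominant AU's presence — and supports exact noiseless recovery arguments
for the dominant stage. It does not model perceptual similarity between
AUs, context effects, drift over an hour-long session, cultural variation
between observers, or rendering artifacts. Passing recovery tests
therefore validate the estimator's arithmetic and the design's information
content, not any claim about human observers.

One property worth stating explicitly: *noiseless* recovery of the
complementary set is not guaranteed. Within the ~7-trial subsets
Ω_{d,j*}, an AU irrelevant to the prototype is borne by the chosen
stimulus about half the time (score ties are resolved by coin), so with
T_q = 0.8 a spurious AU clears the threshold in a nontrivial fraction of
random schedules, and with |C| ≥ 2 a genuine complementary AU can fall
below it when it competes against the other complementary AU. The
recovery tests document exact recovery at fixed seeds and treat the
across-seed behavior statistically (monotone degradation with lapse rate,
chance-level recovery under pure noise at 1/16).

## Problem sizes used by the test suite

Property tests run on 1,000 random 5-AU response sets of up to 15 trials
(partition conservation, brute-force recount equivalence), 200 random
count matrices on 2–6 candidates (exhaustive widest-path oracle), 50
seeds per lapse level for the degradation test and 100 seeds for the
chance-level test, all at the full design scale m = 840. The complete
suite runs in well under a minute.

## Known limitations

* The complementary stage's precision is bounded by |Ω_d| ≈ m·(k/n)²;
  personalizing T_q or enriching the schedule with dominant-AU pairs (an
  adaptive second phase) would help and is not implemented.
* Ballot aggregation assumes complete strict rankings; partial or tied
  ballots are rejected rather than imputed.
* The stub renderer is a schematic placeholder for pipeline smoke tests; a
  real AU-conditioned generator adapter (weights, face crop/alignment) is
  out of scope.
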