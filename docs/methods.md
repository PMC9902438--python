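# Methods

This note records the models `cubkit` implements, the assumptions they
rest on, the defaults and why they were chosen, and what the synthetic
data generator does and does not emulate.

## Representation

All sequences are handled internally in the RNA alphabet (`T` is mapped
to `U` on input) because codon usage tables conventionally spell codons
with `U`.  Frequency vectors live on a single canonical axis: the 64
codons in lexicographic order with `A < C < G < U` (`AAA`, `AAC`, …,
`UUU`).  Every module — counting, testing, ranking, classification —
uses this ordering, so vector positions are comparable across the whole
package.  Triplets containing ambiguity codes (e.g. `N`) are skipped
during counting and tallied, rather than raising: real plasmid and
contig records carry occasional Ns and discarding the whole sequence
would be disproportionate.

The genetic code is configurable (JSON: codon, amino acid, is_start,
is_stop) with the standard code as default — start `{AUG}`, stops
`{UGA, UAG, UAA}` — since some organisms use alternative starts or
reassign stops.

## Potential-ORF enumeration

A potential ORF is any pair (start-codon index, stop-codon index) with
the stop strictly downstream and the separation a multiple of three.
The default `all_pairs` pairing keeps pairs that span intermediate
in-frame stops; this is deliberately permissive — the enumeration is an
upper bound whose purpose is to be thinned by the statistical screen,
and it is what makes candidate counts in the hundreds appear for a
plasmid of a few kb.  `first_stop` (each start paired only with its
nearest in-frame stop) is available for biological realism.  Scanning
defaults to the given strand of a linear sequence; `strand_mode="both"`
also scans the reverse complement (coordinates reported in
reverse-complement frame, `strand='-'`), and `circular=True`
additionally scans the doubled sequence for origin-crossing candidates
(start inside the first copy, span at most the sequence length,
coordinates left unwrapped so `stop >= len(seq)` marks wrapping).
These conventions are flags, not fixed policy, because published
candidate counts for real plasmids do not state them.

## Goodness-of-fit screening

The null hypothesis for each candidate is *its in-frame codon counts
follow the reference organism's codon usage distribution*.

- **Counts from frequencies.**  The chi-square test needs integer
  counts; observed counts are reconstructed as `frequency × n` rounded
  by largest remainder so the total is exactly `n`.  Rounding matters
  only when a frequency vector arrives without its generating counts
  (e.g. from a file); vectors produced by the package's own counting
  round-trip exactly.
- **Zero-frequency reference codons.**  `E_i` in the denominator
  forbids zero expectations, so codons with zero reference frequency
  are removed from both sample and reference, and the expected counts
  are rescaled to the retained observed total (the chi-square test
  requires matched totals).  Degrees of freedom are always
  `retained − 1`.
- **Cressie–Read.**  The power-divergence statistic with the standard
  recommendation `lambda = 2/3` keeps all 64 bins: observed-zero bins
  contribute nothing, and an observation on a zero-expectation bin
  yields an infinite statistic, i.e. certain rejection — the sensible
  limit of "you used a codon this organism never uses".  On zero-free
  data it tracks the chi-square statistic closely (median relative
  difference below 5% in the test suite).
- **Decision rule.**  Reject when the statistic exceeds the
  upper-`alpha` chi-square critical value, equivalently `p < alpha`;
  `alpha` defaults to 0.05.  No multiple-testing correction is applied
  across the candidates of a sequence — raw p-values are always
  reported so users can apply their own; the screen is a pre-filter,
  not an inference about each candidate.
- **Stop codons** are included in candidate frequency vectors by
  default (`include_stop=True`) because reference usage tables include
  stop-codon frequencies; the flag exists because the choice is a
  convention, not a theorem.
- **Subset screening.**  Restricting both sample and reference to a
  codon subset (renormalized, with the effective `n` recomputed from
  retained counts) implements screening on only the most
  taxonomically informative codons.  A candidate with zero observed
  mass on the subset is reported as `untestable`, not an error.  The
  shipped `consensus` subset is the intersection of the top 20 of the
  two published 64-codon influence rankings bundled in
  `data/kingdom_rankings.json` — 11 codons (CUA, GAU, GCG, UGA, CUU,
  AAG, ACA, CGC, AGA, CUG, AGG).

Calibration facts, recomputed by the test suite and
`scripts/acceptance.py`: at 300 codons the Type-I rate sits inside the
exact binomial 99% CI around the nominal 0.05, p-values are
KS-uniform at 1000 codons (distance < 0.1), and sequences generated
from a codon-permuted reference are rejected essentially always at 300
codons.  The chi-square approximation assumes expected counts are not
tiny; at 300 codons over 64 bins the average expectation is ~4.7, and
the small residual Type-I excess that produces is visible but stays
within the CI above.

## Codon influence ranking

- **Lasso path.**  Labels are one-hot encoded; each class column is
  fit one-vs-rest by lasso regression on the 64 raw frequencies at
  every penalty on the grid `1e-8` to `1e-2` in steps of `1e-6`
  (~10^4 points; a 60-point logarithmic grid is available behind
  `coarse=True` for speed and is what the test suite uses).  A codon's
  score is its *survival count*: the number of (class, alpha) fits in
  which its coefficient stays nonzero (`|b| > 1e-12`, so solver dust
  does not count).  Ties break by the larger last-dropout alpha, then
  canonical order.  Two deliberate numerical choices:
  - Alphas are interpreted in scikit-learn's convention (objective
    `1/(2n)||y − Xb||² + alpha||b||₁`).  Under the unscaled objective
    this grid would be vacuous for tables of thousands of rows
    (effective penalties ~1e-10), so the scaled convention is the one
    under which the printed grid does meaningful selection.
  - Features and targets are mean-centered (equivalently, an intercept
    is fit).  Without centering, the class-mean component of the
    one-hot target keeps every coefficient nonzero across the entire
    grid and survival counts stop discriminating; with centering, a
    planted signal codon's dead-zone threshold is ~30× the shuffled-
    label baseline in the test suite's synthetic data.
  Raw frequencies are used unstandardized, matching direct use of
  usage tables; standardization would change the path and is left to
  the caller.
- **Random-forest importance** is mean decrease in impurity from a
  seeded forest (default: the tuned kingdom preset — 1200 trees,
  min-split 2, min-leaf 1, depth cap 100, no bootstrap), normalized to
  sum to 1.
- **Consensus** is the intersection of the two rankings' top-n
  prefixes (default n = 20), reported as an unordered set in canonical
  codon order — a voting step: a codon must look influential to both a
  sparse linear model and a nonlinear tree ensemble.

## Classification

- **k-NN** (from scratch): Euclidean distance, majority label among
  the k nearest, vote fractions (share of neighbours per class)
  exposed as scores for ROC analysis.  Ties go to the class of the
  nearer neighbour, which is deterministic.
- **Gaussian naive Bayes** (from scratch): per-feature Gaussian
  likelihoods, training-frequency priors, variances floored at 1e-9
  (constant features warn).  The independence assumption is knowingly
  false for compositional codon frequencies — the model is kept as a
  worst-case baseline, and behaves like one.
- **SVM / RF / XGB / ANN** are thin seeded wrappers around
  scikit-learn and xgboost with tuned presets per task (kingdom:
  k-NN k=1, SVM RBF C=144 gamma=50, RF 1200/2/1/depth-100/no-bootstrap,
  ANN 600-600-300-150 with l2 6.1e-7; DNA-type: k=3, C=400 gamma=50,
  RF 1088/5/1/no-cap, ANN 700×6-350-175 with 20% dropout-equivalent l2
  6.3e-5).  Re-deriving boosting or backpropagation internals is out
  of scope.  The ANN wrapper uses a multilayer perceptron with early
  stopping (patience 50); it is the one preset the test suite does not
  exercise end-to-end, to keep the default run desk-scale.
- **Ensemble**: hard voting (unweighted plurality; ties to the
  earliest member) over {k-NN, SVM, RF} — adding further members was
  found to hurt test accuracy, so the shipped ensemble stays at three.
- **Metrics** are computed from the confusion matrix with one-vs-rest
  reductions.  Micro averages pool TP/FP/FN before dividing; macro
  averages the per-class ratios; macro-F1 is the harmonic mean of
  macro-precision and macro-recall (note this is *not* the mean of
  per-class F1s and can lie outside their range).  For single-label
  multiclass data micro-F1 equals accuracy — an algebraic identity the
  suite asserts to 1e-12.  Zero-denominator metrics are reported as 0
  with a warning.  AUC is the macro average of one-vs-rest ROC areas
  computed by the trapezoid rule on the threshold-swept ROC (tied
  scores advance along a diagonal segment, scored half-correct); a
  sum of half-rectangle terms alone would score a perfect step ROC as
  0, so the full trapezoid rule is used.  The multiclass reduction
  (macro over one-vs-rest, scores = vote fractions or probabilities)
  is a documented package choice.
- **Splitting** is stratified (default 80/20) and seeded;
  cross-validation is stratified k-fold (k ∈ {3, 5} typical); fold
  disjointness/exhaustiveness is asserted on every run.
- **PCA classification** fits components on the training split only,
  then runs k-NN in the reduced space.  At full rank the metrics equal
  full-space k-NN exactly (Euclidean distance is rotation invariant).
- **K-Means survey** records inertia and mean silhouette per k
  (k ≥ 2; silhouette is undefined at k = 1), seeded, best of 10
  initializations.

## Synthetic data

Codon frequency vectors are compositional, so class-conditional
structure is modeled as Dirichlet draws:

- The **base distribution** is uniform 1/64 perturbed by a seeded
  log-normal factor with sigma 0.6, giving a ~13× ratio between the
  rarest and commonest codon — chosen to match the dynamic range of
  real per-organism usage tables (roughly 10–50× between, say, a rare
  arginine codon and a common leucine codon).  A flat base would
  understate how biased real usage is and make divergence artificially
  hard to detect.
- **Class profiles** interpolate between the shared base and an
  independent Dirichlet(0.5) draw per class:
  `mean_c = (1 − d)·base + d·q_c`, so pairwise total-variation
  distance between class means scales exactly linearly with the
  divergence knob `d ∈ [0, 1]`.
- **Table rows** are `Dirichlet(concentration × mean_c)` draws;
  concentration defaults to 500, putting within-class jitter at a few
  relative percent per codon — tight classes, as real kingdoms are.
- **Sequences**: `gen_codon_sequence` emits i.i.d. codons from a
  reference — the exact multinomial null of the goodness-of-fit test,
  used for calibration.  `gen_coding_sequence` adds gene structure
  (forced start, body restricted to non-stop codons, terminal stop
  drawn from the reference's stop mass); that structure slightly
  distorts the multinomial null, which is why calibration uses the
  plain codon stream and the screening-level check uses a stop-free
  reference (where zero-removal cancels the distortion except for the
  forced start, worth ~0.2 chi-square at 300 codons).
  `gen_plasmid_like` inserts coding sequences at random offsets into
  uniform background and returns their true coordinates.

What the generator does *not* emulate: amino-acid composition
constraints, GC-content gradients, codon-pair effects, mutation or
selection dynamics, length distributions of real genes, or the
phylogenetic correlation structure between organisms.  Tests passing
on this generator therefore demonstrate the statistical machinery is
correct and calibrated under its stated model — not that real genomes
satisfy that model.  Real usage tables can be dropped in via the
CUTG-dialect loader at any point.

## Degenerate inputs and tie-breaks

- Goodness of fit: fewer than 2 retained bins, zero retained counts,
  or an all-zero reference is an error; a zero-mass codon subset is an
  `untestable` flag, not an error, because screening must continue
  past individual untestable candidates.
- Largest-remainder rounding breaks remainder ties by lower canonical
  index.
- Hard-vote ties go to the earliest model; k-NN vote ties to the
  nearer neighbour; ranking ties to larger last-dropout alpha then
  canonical codon order.  All tie-breaks are deterministic so every
  pipeline is reproducible byte-for-byte from (inputs, seed).

## Problem sizes

The default test suite and the acceptance script run entirely on
synthetic data at desk scale: calibration at 500 replicates × 300
codons (KS check at 1000 codons), power at 200 replicates, enumeration
oracle at 200 random sequences up to 300 nt, metric identities at 1000
random matrices/score vectors, ranking recovery over 10 seeds of
2 × 150-row tables with the coarse alpha grid, and classification
recovery on a 5 × 200-row table with the full 1200-tree forest preset.
These sizes give stable Monte-Carlo estimates (binomial CIs quoted
where relevant) while keeping a full run in tens of seconds.
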