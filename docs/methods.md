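# Methods

## Sequence decomposition

A sequence over {A,C,G,T,N} is treated as a realisation of a Markov
chain on nucleotides.  The order-*k* transition *w → b* (prefix *w* a
*k*-mer, emitted base *b*) has conditional frequency
f(w→b) = N(wb) / Σ_b' N(wb'), with N(·) the overlapping occurrence
count; any window containing an N is excluded from numerator and
denominator alike.  Enumerating orders 0..m with m = 5 yields 5460
features in a fixed (order, prefix, base) order.

Two deliberate conventions:

* **Absent prefix ⇒ frequency 0**, not ¼.  Rows stay sparse, a short
  sequence simply has zero blocks at the orders it cannot populate, and
  the downstream t-tests see real zeros rather than imputed values.
* **One strand only.**  Sequences are analysed as oriented gene bodies;
  no reverse-complement aggregation.

An alternative per-length normalisation N(wb)/(#valid windows) is
available (`normalization="length"`); the conditional form is the
default because it is the natural parameter of the Markov chain being
estimated.  The two differ by the prefix marginal, which matters for
interpretation but not for the machinery downstream.

Counting is vectorised: per word length ℓ = 1..m+1 the base-4 codes of
all length-ℓ windows are binned with one `bincount`; conditional rows
are the (4^k × 4) reshape of the (k+1)-mer counts.  The suite pins every
cell against a naive per-position scanning oracle at 1e-12.

## Feature selection

Per feature, Welch's two-sample t-test (unequal variances,
Welch–Satterthwaite df) compares the positive and negative group;
features with two-sided p < α (default 0.05) are *favored* (positive
mean higher) or *disfavored* (lower).  No multiple-testing correction is
applied in the pipeline's selection step — the raw-α rule is part of the
protocol being studied, and the label-shuffle ensemble (below) is the
instrument that quantifies what that rule yields by chance.  Columns
with zero variance in both groups are reported untestable rather than
given an arbitrary p.  The direction of the published test (one- or
two-sided) is not stated; two-sided with sign-assigned direction is the
default and a one-sided flag exists.

Null reference: the group labels are shuffled (group sizes preserved)
`n_sets` times (default 1000) and selection is repeated; per-level
favored/disfavored counts give Q1/Q3 boxes and empirical per-level
p-values by the r/n rule — the fraction of shuffle sets with a count at
least as large.  The r/n rule (not (r+1)/(n+1)) is the default
throughout because the published level-6 value 203 vs 7/1000 ⇒ 0.007
implies it; the +1 correction is available behind a flag.

## Quad-tree and consecutive paths

All transitions form the edge set of a complete 4-ary tree of height
m+1: node = k-mer, root = empty string, the edge for w→b joins node w to
node wb, so order-k edges occupy level k+1.  A consecutively
favored (disfavored) path is a parent-to-child chain of ≥2 edges all
selected in the same direction.  Minimum length 2 is a definition
choice: a single edge is not a "path" of connected transitions.  Runs
are enumerated maximally from each chain-leaf upward, so two branches
sharing upper edges count as two runs while their shared edges count
once in the covered set; `fraction_in_paths` = covered/selected.

The enrichment test redraws, `n_perm` times (default 1E+06; desk-scale
runs use thousands), the same number of edges per level uniformly
without replacement within each level, and reports the fraction of
permutations whose covered fraction reaches the observed one (r/n rule
again).  Permutations are batched as boolean level arrays with the
chain depth/height computed by two level-wise sweeps, so a batch of
thousands of permutations costs a handful of vectorised passes.
Because the covered count is integer-valued, the test statistic is
discrete; calibration checks against Uniform(0,1) use a large selected
set (hundreds of edges across all levels) so the null distribution is
near-continuous — with few selected edges the empirical P is valid but
visibly atomic.

## Classification

ROC/AUC uses the rank statistic (ties at half weight), identical to the
Mann–Whitney U up to scaling; curves sweep unique score thresholds.
Backends behind `ModelSpec`:

* `random_forest` (default) and `gbm` — scikit-learn regressors fit on
  0/1 labels with `n_trees` = 500 by default, following the
  regression-trees formulation of the original protocol (a Bayesian
  additive regression trees implementation is not among the supported
  dependencies; the ensemble regressors are the documented stand-in,
  and the CV protocol, not the learner, is the contract under test);
* `consistency` — the parameter-free consistency score (favored-column
  sum minus disfavored-column sum).  Having a fit-free backend isolates
  protocol effects (leakage) from learner effects, and it stands in for
  the empirical classification models whose exact definitions live
  outside the main text of the source protocol.

Cross-validation is stratified k-fold (default k = 10, shuffled with a
fixed seed; stratification is our choice, the source is silent).
*non_blind* selects features once on all rows, then cross-validates the
model — the selection step sees every test fold.  *fully_blind*
re-selects inside each training fold; a fold whose selection is empty
scores its test rows with an uninformative constant.  Pooled
(out-of-fold scores concatenated) and per-fold AUCs are reported.
Cross-species prediction trains selection + model on one matrix and
scores another with identical columns; no CV.

## Fragments and conservation

Each positive sequence is scanned with a 500-bp window (default step 1;
larger strides are a speed knob).  The window score is the local
consistency score with all frequencies computed **on the window
subsequence alone** — a window is scored as a standalone fragment, so
transitions straddling the edge do not count.  The max-scoring window
(leftmost on ties) is the favored fragment, the min-scoring one the
disfavored fragment; sequences shorter than the window are skipped with
a warning.  Conservation is compared by a two-sided paired t-test on
per-fragment mean scores (identical pairs degenerate to p = 1; a
constant nonzero shift is flagged degenerate with undefined statistic).
The element-overlap test counts a fragment as overlapping at ≥1 bp
intersection and builds its null by placing one uniform random window
per host sequence per simulation (default 1E+05 simulations), one draw
per host per round.  The label-shuffle FPR estimate reruns
selection → fragment calling → paired test on shuffled labels and
reports the fraction of shuffles with a smaller p than observed.

## K-mer baseline and length stratification

K-mer frequencies (K = 1..6) are counts over valid windows divided by
the number of valid window positions (L−K+1 for N-free sequences; the
difference from dividing by L is negligible at these lengths but the
valid-position denominator is the exact reading of "normalised by
length").  The same selection, CV and AUC machinery applies unchanged.
Length-stratified evaluation splits **each class at its own median
length** (the published per-group cutoffs imply per-class medians) into
moderately- and extremely-long halves, ties broken by input order, and
computes the AUC within each stratum.

## TSS orientation

Given aggregate promoter-mark (H3K4me3-style) signals at a gene's two
ends, the higher-signal end is called the TSS; equal signals return
"ambiguous" and the caller keeps the annotated orientation (the rule's
published accuracy is ~86% and no tie rule is stated).  The aggregation
window around each end is a parameter without a default, since none is
published.

## Synthetic benchmark

The generator emulates the data regime the pipeline targets: two groups
of long sequences with lognormal lengths (default median 5 kb, log-sd
0.4, floor 1.5 kb — the real gene bodies are ~33 kb mean/15.8 kb median
with larger spread; everything is scaled down so a benchmark runs in
seconds), drawn from a mildly AT-rich, CpG-depleted order-1 background.
Signal modes:

* **global_shift** — positives are drawn from a model whose chosen
  transitions have conditional probability shifted by ±δ (default
  0.22), renormalised within the context row;
* **planted_fragment** — positives are background except for a fixed
  number of 500-bp fragments from the shifted model, placed uniformly
  without overlap (sorted-gap construction).

`balanced_signal_set` is the default truth set for recovery
experiments: pairs of sibling contexts (A+core vs C+core) receive
exactly opposite ±δ shifts on the same two bases, so every lower-order
conditional cancels identically and the planted transitions are the
*complete* mathematical truth set — without this balancing, any shift
at order k genuinely propagates into the order-(k−1), (k−2), …
conditionals that share the context suffix, and "precision against the
planted list" stops being well-defined.  Cores are additionally
screened for at-least-uniform stationary abundance of both contexts
under the background (an order-≤1 approximation), since a shift planted
in a context the background rarely visits is invisible at benchmark
sequence lengths; recovery experiments evaluate selection at a
Bonferroni-style α = 0.05/5460 so that the comparison against the
planted list is not swamped by the ~α·5460 chance calls the raw rule
produces by design.  `cfp_signal_set` (one full root-to-leaf path plus
scattered deepest-level transitions, mirroring the observed
deepest-level dominance) exercises the quad-tree path statistics.

What the generator does **not** emulate: repeat structure, isochore and
GC gradients, real conservation tracks (the bundled random track is
independent of sequence by construction — exactly what the calibration
tests require and nothing more), annotation noise, and the
assay-derived label noise of real positive/negative sets.  Passing
recovery tests therefore demonstrate correctness and calibration of the
machinery, not expected performance on real genomes.

## Numerical and protocol choices

* Coordinates are 0-based half-open everywhere, including BED output.
* Empirical p-values use r/n by default (matches the published 0.007);
  `add_one=True` gives (r+1)/(n+1).
* Welch statistics are computed vectorised from the textbook formulas;
  scipy equivalents serve as test oracles only.
* Fold assignment, permutations and sequence sampling all derive from
  explicit integer seeds; identical seeds give identical artifacts,
  including the run manifest hash.
* Desk-scale defaults in tests and the acceptance script (hundreds of
  permutations per test, 20 CV replicates, 100-sequence benchmarks) are
  the package's chosen problem sizes; the protocol-scale defaults
  (1000 shuffle sets, 1E+06 permutations, 1E+05 overlap simulations)
  remain the library/CLI defaults.

## Known limitations

* Conditional frequencies of high-order transitions are noisy for short
  sequences (few prefix occurrences); the absent-prefix-⇒-0 convention
  makes this explicit rather than hiding it behind imputation.
* The permutation enrichment P is discrete for small selected sets.
* The end-signal TSS rule has no tie-breaking beyond "ambiguous".
* BigWig score tracks are not read natively; convert to bedGraph or
  fixed-step wiggle.
* The fully-blind CV result depends on the within-fold selection count;
  with very small groups entire folds may select nothing and score as
  uninformative, which is reported, not masked.
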