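# Methods

This note documents the model, the algorithmic choices that were
genuinely open, the synthetic-data generator, and the limits of what the
test suite demonstrates.

## Vector-symbolic encoding

Atomic hypervectors are bipolar (`±1`) arrays of length `d`. The level
family quantising `[v_min, v_max]` into `L` bins starts from a
uniform-random base vector; each subsequent level flips
`N = ⌊d / 2 / L⌋` coordinates drawn without replacement from positions
never flipped in an earlier step (all `(L−1)·N` flip positions are
pre-sampled). Disjoint flip sets are a deliberate choice: they make the
similarity decay exact rather than approximate,
`cos(ℓ_i, ℓ_j) = 1 − 2N|i−j|/d`, which keeps adjacent levels similar,
distant levels quasi-orthogonal, and the geometry testable in closed
form. Re-flipping already-flipped positions would only weaken the
monotonicity.

Quantisation uses uniform half-open bins of width `(v_max − v_min)/L`,
with the last bin closed so `v_max` maps to level `L−1`. `v_min`/`v_max`
default to the observed data range: 0–100 for relative abundances, 0–1
for binary data, where `L = 2` gives the natural mapping 0 → level 0,
1 → level 1. Two different values falling in one bin share a level
vector by design — that is the resolution/robustness trade-off `L`
controls.

Rotation is a right circular shift (`index i → (i+p) mod d`). Any fixed
bijective convention works; this one was chosen for testability.
Sample encodings and class vectors are kept as exact integer sums — no
thresholding or sign normalisation — so the retraining bookkeeping
(below) reconciles exactly, and cosine similarity absorbs magnitude
differences.

## Classifier and retraining

Class vectors are the integer sums of their training samples'
encodings. Prediction is cosine-argmax over the class vectors, with
exact ties broken by sorted label order (determinism matters more than
the choice itself). An all-zero class vector makes cosine undefined and
raises an error naming the class rather than guessing.

Retraining runs at most `R` passes (default 10). Within a pass, samples
are visited in dataset order and every misclassification *immediately*
subtracts the sample's encoding from the wrong class vector and adds it
to the true one (online updates). Convergence is tested after each pass
on the full training set: the loop stops when the integer error count
equals the previous pass's count — an equality test, no tolerance. The
initial class vectors and the full adjustment log are retained on the
model so the final vectors can be replayed and verified exactly.

Cross-validation is stratified by class label and seeded; the level
registry is built once per dataset from the global value range and
shared across folds, because levels encode values, not samples —
rebuilding per fold would make fold accuracies incomparable.

## Backward variable elimination

Per iteration, one candidate model per missing feature is evaluated by
k-fold cross-validated accuracy (default k=5). Control flow:

1. Evaluate the full feature set; if its accuracy is below the threshold
   `T` (default 0.60) there is not enough signal to justify removals and
   the algorithm returns immediately.
2. Each iteration evaluates all `|S|` candidates, discards those below
   `T`, and removes *every* feature whose candidate accuracy is at least
   `ACC* · (1 − u/100)` — the uncertainty band below the iteration best,
   `u` in percent (default 1). The band threshold is computed in exact
   arithmetic, not rounded. A strict single-removal mode
   (`multi_removal=False`) removes only the iteration best, breaking
   ties by feature order.
3. After the removal, the iteration best is compared against the
   previous iteration's best; elimination stops when it is lower. It
   also stops when no candidate reaches `T` or when `S` is exhausted.

Band multi-removal is the default because removing only one feature per
iteration wastes a full sweep on each of several near-equivalent
candidates; the band collapses them into one iteration. The result
reports the surviving set, the removal bucket in order, the full
per-candidate history, the globally best subset (ties: fewest features,
then lexicographic), and the *sub-optimal* record — the evaluated subset
with the fewest features whose accuracy strictly exceeds the 70% floor
(ties: higher accuracy, then lexicographic).

Two reproducibility choices deserve note. First, every candidate
subset's CV seed is derived from a hash of the global seed and the
*sorted* subset, so results are independent of evaluation order and of
the worker count used for parallel evaluation. Second, subsets are
always encoded with features in sorted-name order; rotation amounts are
positional, so without this canonicalisation the same subset would
encode differently depending on input column order. With it, permuting
the input columns changes nothing.

`models_evaluated` counts fold-models: k × the number of distinct
subsets evaluated (one per history row). When an injected accuracy
oracle replaces HD training — a hook for exercising the control flow
against a known trace — it counts one lookup per subset. Candidates
below `T` are kept in the history, flagged, since the history also
feeds the sub-optimal scan.

## Preprocessing

Multi-study harmonisation keeps only species detected (abundance > 0 in
at least one sample) in every study; excluded species' abundances are
added per sample to the `unclassified` remainder, so per-sample totals
are conserved — a property every abundance-moving filter maintains and
the suite asserts. The low-abundance filter removes species whose
**maximum** abundance across samples is below the threshold (default
1%); max is the most conservative remover and a `mean` criterion is
exposed as an option since the statistic is a judgement call. The
prevalence filter removes species detected in strictly fewer than 5% of
samples (4 of 100 goes, 5 of 100 stays). Detection always means
strictly positive abundance, mirroring binarisation (`1 if value > 0`).
Stratification splits by biological sex or by age category with adult
meaning age ≤ 65 and senior age > 65; samples missing the
stratification value are excluded and reported.

## Differential abundance

Prevalence is the percentage of in-class samples with the species
present. log2FC is `log2(mean_case / mean_control)` on
relative-abundance values even when selection ran on binarised data;
zero means yield IEEE flags (±inf/nan), not exceptions. The rank-sum
test uses the exact null distribution when the pooled sample is ≤ 50
and tie-free, otherwise the normal approximation with tie correction; a
species constant across all pooled samples gets p = 1 with a degenerate
flag. BH correction spans the full tested family (all surviving
species) by default — the defensible choice when the family is not
otherwise specified — and an absolute-log2FC ≥ 1 pre-filter can
optionally be applied before or after the correction; after is the
default. Significance is the conjunction p ≤ 0.05 and FDR ≤ 0.2.

## Synthetic cohorts

The generator emulates a balanced case/control stool cohort: defaults
are 60/60 samples and 30 species of which 3 are informative, present in
80% of cases versus 10% of controls, against a 50% background — a
strong but noisy planted signal. Present-species magnitudes are
log-normal(μ=0, σ=1) (heavy-tailed, like real relative abundances); the
unclassified remainder is log-normal(μ=3, σ=0.5), typically the largest
single component, and each sample is rescaled so species plus
unclassified total exactly 100. Sex is uniform and age uniform over
28–84 years, matching a typical colorectal-cancer cohort span; metadata
does not influence abundances unless a stratum effect is configured, so
stratification tests cannot leak.

What the generator does **not** emulate: ecological covariance between
species (features are independent given class), compositional coupling
beyond the closure to 100, study batch effects, and
sequencing/profiling noise. Passing tests therefore demonstrate that
the algorithms behave as specified on independent planted signals — not
that comparable accuracy would be reached on real cohorts, where
correlated taxa and batch structure make selection harder.

## Operating sizes and numerics

Default operating point: d = 10,000; L = 1,000 for relative-abundance
data and 2 for binary; R = 10; k = 5; T = 60%; u = 1%; sub-optimal
floor 70%. The heavy replicate checks (planted recovery and the null
control, 10 seeds each) run at d = 1,024 with binary levels — for
presence/absence data accuracy saturates well below d = 10,000, and the
smaller dimensionality keeps a full 10-replicate elimination sweep
around a minute. Accuracies are serialised as fractions with 6
decimals; percentages appear only in human-readable logs. All
randomness flows through seeded `numpy` generators; per-subset seeds
stay below 2^31.

## Known limitations

- Wrapper selection cost is quadratic in the feature count; thousands
  of features need the parallel evaluator and patience.
- The uncertainty band is relative to the iteration best, so with very
  flat accuracy landscapes (e.g. null data just above T) it can remove
  many features at once; the previous-best stopping rule is the
  backstop.
- Binary encoding with L = 2 makes the two levels 0.5-similar by
  construction; absent species therefore still contribute signal, which
  is intended (absence is informative) but differs from a sparse
  presence-only encoding.
- The retraining error trace is not guaranteed monotone; only
  stabilisation is guaranteed, and oscillating traces simply run to the
  pass budget.
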