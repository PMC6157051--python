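# Methods

## Data model

A call set maps variants, keyed by (chromosome, 1-based position), to the
subset of callers that predicted them. Alleles, genotypes and read-level
evidence are outside the model: the selection and evaluation mathematics
depend only on membership structure and truth labels. Chromosome labels
are opaque strings ("chr1" ≠ "1"); readers accept a `normalize_chrom`
toggle that strips a leading "chr". Duplicate (caller, variant) records
collapse to a single call. Truth tables refuse lookups of unlabelled
variants — a silent default would corrupt confusion counts.

## Selection strategies

All six strategies share one contract: given a budget `n_targets`, the
selection contains exactly `min(n_targets, |union|)` distinct variants
and is a pure function of (profile, budget, seed).

Where the allocation rules leave choices open, the package resolves them
as follows:

* **Integerization.** Fractional quotas use largest-remainder
  apportionment: each unit gets `floor(share)`, and the leftover units go
  one each to the largest fractional remainders, exact ties broken by a
  seeded shuffle. This conserves the budget exactly without a systematic
  bias toward any caller or level.
* **Shortfall redistribution.** When a caller or overlap level cannot
  fill its quota, the unspent budget is re-apportioned *equally* over the
  units that still have unconsumed calls, iterating until the budget is
  spent or no calls remain. The first pass uses the strategy's own
  weights (1, k, or 1/k per level); only redistribution passes are equal,
  reflecting the usual description of shortfall handling as "distributed
  equally to the others". Iteration (rather than a single redistribution)
  is needed to preserve the budget contract under cascading shortfalls.
* **Processing order.** Callers (in `equal_per_caller`) and tie-broken
  cells (in `directed_sampling`) are ordered by a seeded shuffle, fixed
  for the run. Order matters only where pools share calls; randomizing it
  avoids systematically advantaging any caller across replicates.
* **Directed sampling.** The overlap-by-caller matrix is traversed from
  row N down to row 1, cells within a row by ascending available pool
  size. The cell budget is `floor(remaining / unexamined)` where
  `unexamined` counts the cells not yet visited in this pass that held
  calls at pass start. Selected calls are invalid for later cells. Passes
  repeat while budget and selectable calls remain; if floor quotas starve
  an entire pass (possible when remaining < number of cells), a fallback
  pass grants one selection per non-empty cell in traversal order. This
  guarantees termination and full budget use. A consequence of the floor
  rule: when the budget is smaller than the number of non-empty cells,
  the early (high-overlap) cells receive budget 0 and the selection
  concentrates in the cells visited last.
* **RNG.** Strategies use Python's `random.Random`, one instance per
  selection, seeded explicitly; the seed is recorded in the selection
  output. Stream separation elsewhere uses string-tagged seeds or a
  BLAKE2-based `derive_seed(master, *coords)`, so every replicate is
  reproducible in isolation.

## Evaluation

Scoring classifies selected variants only: TP (caller predicted, true),
FP (caller predicted, false), FN (caller did not predict, true). False
selected variants the caller did not predict contribute nothing.
Precision is N/A iff TP+FP = 0, recall N/A iff TP+FN = 0, and F1 is N/A
iff either factor is; when precision and recall are both defined and
zero, F1 is 0, reserving N/A strictly for "nothing to estimate from".

Weighted precision stratifies the caller's selected calls by overlap
level, computes per-level precisions, and averages them weighted by the
caller's *total* call count per level. Levels at which the caller has
calls but none selected are excluded from numerator and denominator
(their group precision is undefined; inventing one would require a prior
on unsampled strata). Weighted mode changes precision only; recall and
the F1 formula are unchanged.

Full-set ("true") baselines: `union` scores each caller over the entire
call union — the exact limit of any strategy at an unbounded budget, used
for convergence and recovery checks; `all-mutations` (the default for
benchmarking) additionally counts true mutations predicted by *no* caller
in every caller's FN, measuring recall against the complete mutation set.
Precision is identical under both. Full-set records are mode-independent:
with every call selected, the weighted average reduces algebraically to
default precision (weights equal realized group sizes), so subset scores
in either mode are compared against the same full-set F1.

## Synthetic ensembles

The generator abstracts the axes of difficulty of real tumour data
(contamination, sub-clonality, mutation rate) into the only quantities
the selection/evaluation math is sensitive to: per-caller sensitivity,
per-caller false-positive load, and correlated (recurrent) false
positives. Caller k detects each of `n_true` true mutations independently
with probability `sensitivity_k` and adds `n_false_positives_k` false
calls, a `shared_fp_fraction` of them drawn from a common pool of
`fp_pool_size` recurrent-error positions (overlapping draws across
callers create multi-caller false calls), the rest private. True, pool
and private coordinates are disjoint slices of one global draw over a
10 Mb abstract chromosome, so labels are unambiguous by construction.
Generation is a pure function of the config seed.

Three stock configurations define the study conditions:

* **Default 3-caller ensemble** — sensitivities 0.95/0.85/0.75, FP loads
  1500/1000/500, 6000 true mutations, shared FP fraction 0.3 over a
  1000-position pool; ≈ 8.8k union calls. A small, strongly heterogeneous
  ensemble where strategy differences are visible; used for the ΔF1
  convergence experiment at budgets 100–2500.
* **Submission pool** (`submission_pool_config`) — 15 callers on an even
  sensitivity ladder 0.75–0.95 with FP loads 100–600, 5000 true
  mutations; ≈ 9.7k union calls. Sized like a benchmarking challenge's
  submission collection; used for parameter recovery at budget 2500. With
  this many callers, per-level composition biases average out enough that
  recovery is informative about estimator consistency rather than about a
  single caller's idiosyncrasy.
* **Skewed ensemble** (`skewed_config`) — one dominant caller (sensitivity
  1.0 padded with private FPs to 10,000 calls) plus two ~10-call minor
  callers over 2000 true mutations. Reproduces the regime where uniform
  random sampling misses a small call set entirely.

What the generator does **not** emulate: sequence-context error
correlation, allele-level identity, caller-specific overlap structure
beyond the shared-FP pool, and verification-assay error (verification
results are assumed to be ground truth). Passing tests therefore
demonstrate the statistical behaviour of the selection/estimation
machinery, not calling accuracy on real reads.

## Benchmark harness

A sweep crosses datasets × caller subsets × budgets × strategies ×
precision modes × replicates. Caller subsets follow the four standard
modes (complete; best per team, requiring an explicit caller→team map;
k random from the best-per-team pool; k random from all), with random
modes replicated; with all four modes at 10 replicates a dataset
contributes 22 subsets, and 3 datasets × 5 budgets give 330
configurations. Per-row seeds derive from the master seed and the row's
factor coordinates via BLAKE2, so replicates are independent yet
individually reproducible. N/A rows are flagged, excluded from location
and spread statistics, and surfaced as a per-strategy N/A rate.
Strategies are ranked by median |ΔF1| ascending, ties broken by IQR then
name; a strategy with no defined scores ranks last and is flagged.
Medians of signed ΔF1 are reported alongside; ranking uses the magnitude.

## Experiment sizes

The shipped experiments run at desk scale: ensembles of ~10⁴ calls,
10 replicates per cell, 200 seeds for frequency comparisons, and
exhaustive enumeration capped at 3 callers × 6 variants (≈1800 canonical
profiles × 6 strategies × 50 seeds) — sizes at which binomial and
hypergeometric 3σ bands are tight enough to be informative while the full
suite completes in well under a minute of compute per module.

## Known limitations

* **Subset recall is not design-unbiased for structured strategies.**
  Any strategy that over-represents a caller's calls relative to the
  union inflates that caller's estimated recall: the selected "true calls
  not made by the caller" shrink relative to its TPs. The effect is
  extreme for `equal_per_caller` on heavily skewed ensembles — a 10-call
  caller gets all its calls selected while the 10,000-call caller is
  subsampled, so the small caller's recall estimate can be off by orders
  of magnitude (measured subset recall ≈ 0.23 against a true 0.0025).
  Consequently, on such ensembles `equal_per_caller`'s mean |ΔF1| is
  substantially *worse* than `random_rows`' over the rows where
  `random_rows` produces estimates at all; `equal_per_caller`'s advantage
  is that it always produces an estimate for every caller (zero N/A
  rate), whereas `random_rows` misses small call sets at the
  hypergeometric rate. The weighted adjustment corrects precision, not
  recall; no analogous reweighting is implemented for recall.
* **Overlap-stratified recall biases grow with caller heterogeneity.**
  With few, strongly dissimilar callers, per-caller recall recovery
  errors for `decreasing_with_overlap` and `directed_sampling` reach
  0.07–0.16 at budget 2500; with 15+ callers they fall below 0.04. The
  recovery experiment is therefore defined on the submission pool, and
  `decreasing_with_overlap` — which concentrates the budget on unique
  calls — consistently shows the poorest recall recovery.
* Variant identity is positional; multi-allelic sites collapse.
* Verification results are treated as error-free; assay noise would bias
  all strategies alike and is out of scope.
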