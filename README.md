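# veriselect

Budget-constrained selection of verification candidates from multi-caller
variant call sets, with per-caller precision/recall/F1 estimation from the
verified subset and a benchmarking harness for comparing selection
strategies against known ground truth.

## The problem

Somatic SNV calls from high-throughput sequencing carry substantial false
positive and false negative rates, so predictions are commonly *verified*
by re-testing the same sample on an orthogonal platform. Verifying every
call is expensive; in practice a subset is verified and each caller's
error profile is inferred from it. Which subset you pick matters: a
uniform random draw can miss a small call set entirely, while structured
draws can bias the inferred scores. `veriselect` is for groups running
such verification studies — and for methodologists benchmarking callers —
who need a principled, reproducible way to spend a verification budget of
`n_targets` calls across `N` callers.

## The method

Calls are keyed by (chromosome, position). A variant's **overlap level**
`k` is the number of callers that predicted it. Six strategies allocate
the budget, all sampling without replacement and always selecting exactly
`min(n_targets, |union of calls|)` variants:

| strategy | allocation |
|---|---|
| `random_rows` | uniform over the call union |
| `equal_per_caller` | budget split equally over callers; a call taken for one caller is invalid for the rest |
| `equal_per_overlap` | split equally over overlap levels 1..N |
| `increasing_with_overlap` | level-k quota ∝ k |
| `decreasing_with_overlap` | level-k quota ∝ 1/k |
| `directed_sampling` | walks the overlap-by-caller matrix (rows N→1, cells by ascending size), spreading the remaining budget over unexamined cells |

Fractional quotas are integerized by largest-remainder apportionment with
seeded tie-breaks; shortfalls are redistributed equally over units that
still have calls.

Treating verification results as ground truth, each caller is scored over
the selected variants only, with

  precision = TP / (TP + FP),  recall = TP / (TP + FN),
  F1 = 2 · precision · recall / (precision + recall),

where FN counts selected true variants the caller did *not* predict. A
caller with no selected calls gets N/A scores. Precision also has a
**weighted** mode: per-overlap-level group precisions are averaged with
weights equal to the caller's total call count at each level, which
corrects the composition bias of the stratified strategies (a caller with
100 unique and 50 shared calls weighs its unique-call precision twice as
strongly). The quality of a strategy is summarized by ΔF1 = subset F1 −
full-set F1 per caller, aggregated over replicate runs.

## Worked example

Simulate a 3-caller ensemble with known truth, select 500 candidates with
`equal_per_caller`, and compare subset estimates to the full-set scores:

```sh
veriselect simulate --out-calls calls.csv --out-truth truth.csv --seed 7
# wrote 8750 calls from 3 callers (6000 true mutations) to calls.csv, truth to truth.csv
veriselect select --calls calls.csv --budget 500 --strategy equal_per_caller \
    --seed 7 --output selection.tsv
# equal_per_caller: selected 500 of 8750 calls (budget 500) -> selection.tsv
veriselect evaluate --calls calls.csv --truth truth.csv \
    --selection selection.tsv --mode weighted --output est.tsv
veriselect evaluate --calls calls.csv --truth truth.csv \
    --baseline union --output full.tsv
```

`est.tsv` (estimates from the 500 verified calls):

```
caller    mode      TP   FP  FN  precision  recall  F1
caller_A  weighted  416  42  12  0.7878     0.9720  0.8703
caller_B  weighted  389  24  39  0.8465     0.9089  0.8766
caller_C  weighted  353  19  75  0.8967     0.8248  0.8592
```

`full.tsv` (true scores over all 8750 calls):

```
caller    mode     TP    FP    FN    precision  recall  F1
caller_A  default  5708  1500  280   0.7919     0.9532  0.8651
caller_B  default  5077  1000  911   0.8354     0.8479  0.8416
caller_C  default  4436  500   1552  0.8987     0.7408  0.8122
```

From 500 verified calls (5.7% of the union), the weighted-mode precision
estimates land within 0.01 of truth for every caller; ΔF1 stays within
0.05. The `sweep` and `rank` subcommands automate this comparison across
strategies, budgets, caller subsets and replicates from a YAML config,
and real call sets can be supplied as prediction-by-submission matrices
(CSV: `CHROM,END,<submission...>` with 0/1 flags) or long tables
(`caller,chrom,pos`), with truth as `chrom,pos,truth` CSVs.

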