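"""Per-caller precision, recall and F1 estimated from a verified subset.

The verification study treats the verified labels as ground truth and
classifies only the *selected* variants:

* TP — selected, called by the caller, true;
* FP — selected, called by the caller, false;
* FN — selected, true, but not called by this caller (i.e. another caller
  made it and it verified as real);

precision = TP / (TP + FP), recall = TP / (TP + FN), and F1 is their
harmonic mean. When a selection contains no calls from which a score can
be computed (TP + FP = 0 for precision, TP + FN = 0 for recall), the score
is undefined and recorded as N/A (``None``); F1 is N/A when either factor
is. If precision and recall are both defined and zero, F1 is 0.

Two precision modes exist. ``default`` pools all selected calls of the
caller. ``weighted`` first groups the caller's selected calls by overlap
level, computes a per-group precision, and averages the groups with
weights equal to the caller's *total* (verified and unverified) call count
at each level — so precision on unique calls, which dominate most call
sets, counts proportionally to how many unique calls the caller made.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import CallProfile, Selection, TruthTable, VariantKey

Score = float | None  # None encodes the N/A (undefined) score


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN over the selected variants, for one caller."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class MetricsRecord:
    """One caller's estimated scores under one precision mode."""

    caller: str
    mode: str
    tp: int
    fp: int
    fn: int
    precision: Score
    recall: Score
    f1: Score

    @property
    def counts(self) -> ConfusionCounts:
        return ConfusionCounts(self.tp, self.fp, self.fn)


def confusion_counts(
    caller: str,
    profile: CallProfile,
    selection: Selection,
    truth: TruthTable,
) -> ConfusionCounts:
    """Classify the selected variants for one caller.

    Selected false variants not called by the caller contribute nothing.
    Raises ``KeyError`` if a selected variant has no truth label.
    """
    tp = fp = fn = 0
    for v in selection.variants:
        called = caller in profile.membership.get(v, frozenset())
        is_true = truth[v]
        if called and is_true:
            tp += 1
        elif called:
            fp += 1
        elif is_true:
            fn += 1
    return ConfusionCounts(tp, fp, fn)


def _precision(tp: int, fp: int) -> Score:
    return None if tp + fp == 0 else tp / (tp + fp)


def _recall(tp: int, fn: int) -> Score:
    return None if tp + fn == 0 else tp / (tp + fn)


def _f1(precision: Score, recall: Score) -> Score:
    if precision is None or recall is None:
        return None
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def precision_recall_f1(counts: ConfusionCounts) -> tuple[Score, Score, Score]:
    """(precision, recall, F1) with N/A (None) propagation."""
    p = _precision(counts.tp, counts.fp)
    r = _recall(counts.tp, counts.fn)
    return p, r, _f1(p, r)


def overlap_group_weights(caller: str, profile: CallProfile) -> dict[int, int]:
    """The caller's total call count at each overlap level it occupies.

    These are the weights of the weighted-precision average: a caller with
    100 unique calls and 50 two-caller calls weighs its unique-call group
    precision twice as strongly as its shared-call group precision.
    """
    return profile.level_counts(caller)


def weighted_precision(
    caller: str,
    profile: CallProfile,
    selection: Selection,
    truth: TruthTable,
) -> Score:
    """Overlap-stratified precision.

    Selected calls of the caller are grouped by overlap level; each group's
    precision is averaged with weight = the caller's total call count at
    that level. Levels with no selected call of the caller are excluded
    from both numerator and denominator (their group precision is
    undefined). Returns None when the selection contains no call of the
    caller.
    """
    group_tp: dict[int, int] = {}
    group_n: dict[int, int] = {}
    for v in selection.variants:
        group = profile.membership.get(v, frozenset())
        if caller not in group:
            continue
        level = len(group)
        group_n[level] = group_n.get(level, 0) + 1
        if truth[v]:
            group_tp[level] = group_tp.get(level, 0) + 1
    if not group_n:
        return None
    weights = overlap_group_weights(caller, profile)
    num = sum(weights[g] * (group_tp.get(g, 0) / n) for g, n in group_n.items())
    den = sum(weights[g] for g in group_n)
    return num / den


def evaluate_caller(
    caller: str,
    profile: CallProfile,
    selection: Selection,
    truth: TruthTable,
    mode: str = "default",
) -> MetricsRecord:
    """Estimate one caller's scores from the selection."""
    if mode not in ("default", "weighted"):
        raise ValueError(f"mode must be 'default' or 'weighted', got {mode!r}")
    counts = confusion_counts(caller, profile, selection, truth)
    p, r, f1 = precision_recall_f1(counts)
    if mode == "weighted":
        p = weighted_precision(caller, profile, selection, truth)
        f1 = _f1(p, r)
    return MetricsRecord(
        caller=caller,
        mode=mode,
        tp=counts.tp,
        fp=counts.fp,
        fn=counts.fn,
        precision=p,
        recall=r,
        f1=f1,
    )


def evaluate_all_callers(
    profile: CallProfile,
    selection: Selection,
    truth: TruthTable,
    mode: str = "default",
) -> list[MetricsRecord]:
    """One record per caller, in profile caller order."""
    return [
        evaluate_caller(c, profile, selection, truth, mode) for c in profile.callers
    ]


def full_set_metrics(
    profile: CallProfile,
    truth: TruthTable,
    baseline: str = "all-mutations",
) -> list[MetricsRecord]:
    """The "true" scores the subset estimates are compared against.

    baseline="union" scores each caller over the entire call union, i.e.
    the limit of any selection strategy at an unbounded budget.
    baseline="all-mutations" (default) additionally counts, in every
    caller's FN, the true mutations that no caller predicted, so recall is
    measured against the complete mutation set. Precision is identical
    under both baselines, and the weighted-precision average over the full
    call set reduces algebraically to default precision, so full-set
    records carry mode="default".
    """
    if baseline not in ("union", "all-mutations"):
        raise ValueError(
            f"baseline must be 'union' or 'all-mutations', got {baseline!r}"
        )
    everything = Selection(
        variants=profile.variants,
        attribution={v: "full-set" for v in profile.variants},
        strategy_name="full-set",
        seed=0,
    )
    missed = 0
    if baseline == "all-mutations":
        missed = sum(1 for v in truth.true_variants if v not in profile)
    records = []
    for caller in profile.callers:
        counts = confusion_counts(caller, profile, everything, truth)
        counts = ConfusionCounts(counts.tp, counts.fp, counts.fn + missed)
        p, r, f1 = precision_recall_f1(counts)
        records.append(
            MetricsRecord(
                caller=caller,
                mode="default",
                tp=counts.tp,
                fp=counts.fp,
                fn=counts.fn,
                precision=p,
                recall=r,
                f1=f1,
            )
        )
    return records


def f1_difference(subset: MetricsRecord, full: MetricsRecord) -> Score:
    """Subset F1 minus full-set F1 (ΔF1); None if either score is N/A."""
    if subset.caller != full.caller:
        raise ValueError(
            f"caller mismatch: {subset.caller!r} vs {full.caller!r}"
        )
    if subset.f1 is None or full.f1 is None:
        return None
    return subset.f1 - full.f1
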