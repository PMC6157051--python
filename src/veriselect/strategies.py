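"""The six verification-candidate selection strategies.

All strategies sample without replacement under a shared contract: given a
call profile and a budget of ``n_targets`` candidates, the selection always
contains exactly ``min(n_targets, |union of calls|)`` distinct variants —
the budget is fully spent unless the calls run out — and is a deterministic
function of (profile, budget, seed).

* ``random_rows`` — uniform sampling from the whole call union.
* ``equal_per_caller`` — the budget is split equally across callers; each
  caller samples from its own calls, and a call taken for one caller is
  invalid for the rest.
* ``equal_per_overlap`` — the budget is split equally across overlap
  levels 1..N (level k = calls made by exactly k callers).
* ``increasing_with_overlap`` / ``decreasing_with_overlap`` — per-level
  quotas proportional to k, respectively 1/k.
* ``directed_sampling`` — walks the overlap-by-caller matrix from the
  most-recurrent row down, spreading the remaining budget over the
  not-yet-examined cells.

Fractional quotas are integerized by largest-remainder apportionment with
seeded tie-breaking, so each strategy conserves the budget exactly. When a
unit (caller / level / cell) cannot fill its quota, the unspent budget is
re-apportioned equally over the units that still have calls, repeating
until the budget is spent or nothing selectable remains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from random import Random
from typing import Callable, Hashable, Mapping, Sequence

from .model import Budget, CallProfile, OverlapMatrix, Selection, VariantKey

STRATEGY_NAMES: tuple[str, ...] = (
    "random_rows",
    "directed_sampling",
    "equal_per_caller",
    "equal_per_overlap",
    "increasing_with_overlap",
    "decreasing_with_overlap",
)


@dataclass(frozen=True)
class StrategyConfig:
    """A named strategy plus the seed for its RNG stream."""

    name: str
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in STRATEGY_NAMES:
            raise ValueError(
                f"unknown strategy {self.name!r}; expected one of {STRATEGY_NAMES}"
            )


@dataclass
class AllocationPlan:
    """Integer quotas produced by largest-remainder apportionment.

    ``remainder_order`` lists the units that received the +1 units from the
    fractional remainder, in the order they were granted.
    """

    unit: str
    quotas: dict[Hashable, int]
    remainder_order: list[Hashable] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.quotas.values())


def apportion(
    weights: Mapping[Hashable, float],
    total: int,
    seed: int | Random = 0,
    unit: str = "unit",
) -> AllocationPlan:
    """Largest-remainder apportionment of ``total`` over ``weights``.

    Each unit receives floor(total * w / W); the leftover units go one each
    to the largest fractional remainders, ties broken by a seeded shuffle.
    Quotas always sum to ``total`` exactly.
    """
    if total < 0:
        raise ValueError(f"total must be >= 0, got {total}")
    if any(w < 0 for w in weights.values()):
        raise ValueError("weights must be non-negative")
    wsum = float(sum(weights.values()))
    if wsum <= 0:
        raise ValueError("at least one weight must be positive")
    rng = seed if isinstance(seed, Random) else Random(seed)

    quotas: dict[Hashable, int] = {}
    fracs: list[tuple[float, float, Hashable]] = []
    for key, w in weights.items():
        share = total * (w / wsum)
        base = math.floor(share)
        quotas[key] = base
        fracs.append((share - base, rng.random(), key))
    leftover = total - sum(quotas.values())
    # descending fractional part; random jitter only breaks exact ties
    fracs.sort(key=lambda t: (-t[0], t[1]))
    remainder_order = [key for _, _, key in fracs[:leftover]]
    for key in remainder_order:
        quotas[key] += 1
    return AllocationPlan(unit=unit, quotas=quotas, remainder_order=remainder_order)


def _as_n_targets(budget: Budget | int) -> int:
    n = budget.n_targets if isinstance(budget, Budget) else int(budget)
    if n < 1:
        raise ValueError(f"budget must be >= 1, got {n}")
    return n


def select_random_rows(
    profile: CallProfile, budget: Budget | int, seed: int = 0
) -> Selection:
    """Sample calls uniformly at random without replacement from the union."""
    rng = Random(seed)
    pool = list(profile.variants)
    n = min(_as_n_targets(budget), len(pool))
    chosen = rng.sample(pool, n)
    attribution = {
        v: rng.choice(sorted(profile.membership[v])) for v in chosen
    }
    return Selection(
        variants=tuple(chosen),
        attribution=attribution,
        strategy_name="random_rows",
        seed=seed,
    )


def _select_by_units(
    profile: CallProfile,
    budget: Budget | int,
    seed: int,
    strategy_name: str,
    unit_pools: Mapping[Hashable, Sequence[VariantKey]],
    first_pass_weights: Mapping[Hashable, float],
    label: Callable[[Hashable], str],
    unit: str,
) -> Selection:
    """Shared quota machinery for the caller- and overlap-based strategies.

    The first apportionment pass uses the strategy's weights; shortfall
    passes redistribute the unspent budget equally over units that still
    have unconsumed calls.
    """
    rng = Random(seed)
    order = sorted(unit_pools)
    rng.shuffle(order)  # processing order matters when pools share calls

    union_size = len(profile)
    remaining = min(_as_n_targets(budget), union_size)
    consumed: set[VariantKey] = set()
    chosen: list[VariantKey] = []
    attribution: dict[VariantKey, str] = {}

    first_pass = True
    while remaining > 0:
        active = [u for u in order if any(v not in consumed for v in unit_pools[u])]
        if not active:
            break
        if first_pass:
            weights = {u: first_pass_weights[u] for u in active}
            if sum(weights.values()) <= 0:
                weights = {u: 1.0 for u in active}
        else:
            weights = {u: 1.0 for u in active}
        plan = apportion(weights, remaining, rng, unit=unit)
        spent = 0
        for u in active:
            quota = plan.quotas[u]
            if quota <= 0:
                continue
            avail = [v for v in unit_pools[u] if v not in consumed]
            take = min(quota, len(avail))
            if take == 0:
                continue
            picks = avail if take == len(avail) else rng.sample(avail, take)
            for v in picks:
                attribution[v] = label(u)
            chosen.extend(picks)
            consumed.update(picks)
            spent += take
        remaining -= spent
        if spent == 0:
            break
        first_pass = False
    return Selection(
        variants=tuple(chosen),
        attribution=attribution,
        strategy_name=strategy_name,
        seed=seed,
    )


def select_equal_per_caller(
    profile: CallProfile, budget: Budget | int, seed: int = 0
) -> Selection:
    """Divide the budget equally among callers; each samples its own calls.

    A call selected for one caller becomes invalid for the others, so the
    attributed sets are pairwise disjoint. Callers are processed in seeded
    random order (order matters only where call sets overlap).
    """
    return _select_by_units(
        profile,
        budget,
        seed,
        "equal_per_caller",
        unit_pools={c: profile.calls_of(c) for c in profile.callers},
        first_pass_weights={c: 1.0 for c in profile.callers},
        label=str,
        unit="caller",
    )


def _overlap_strategy(
    profile: CallProfile,
    budget: Budget | int,
    seed: int,
    strategy_name: str,
    weight_of_level: Callable[[int], float],
) -> Selection:
    levels = range(1, profile.n_callers + 1)
    return _select_by_units(
        profile,
        budget,
        seed,
        strategy_name,
        unit_pools={k: profile.variants_at_level(k) for k in levels},
        first_pass_weights={k: weight_of_level(k) for k in levels},
        label=lambda k: f"level={k}",
        unit="overlap-level",
    )


def select_equal_per_overlap(
    profile: CallProfile, budget: Budget | int, seed: int = 0
) -> Selection:
    """Divide the budget equally among overlap levels 1..N."""
    return _overlap_strategy(profile, budget, seed, "equal_per_overlap", lambda k: 1.0)


def select_increasing_with_overlap(
    profile: CallProfile, budget: Budget | int, seed: int = 0
) -> Selection:
    """Per-level quota proportional to the overlap level k."""
    return _overlap_strategy(
        profile, budget, seed, "increasing_with_overlap", lambda k: float(k)
    )


def select_decreasing_with_overlap(
    profile: CallProfile, budget: Budget | int, seed: int = 0
) -> Selection:
    """Per-level quota proportional to 1/k — unique calls dominate."""
    return _overlap_strategy(
        profile, budget, seed, "decreasing_with_overlap", lambda k: 1.0 / k
    )


def select_directed_sampling(
    profile: CallProfile, budget: Budget | int, seed: int = 0
) -> Selection:
    """Walk the overlap-by-caller matrix, spreading budget over its cells.

    Rows are traversed from the most-recurrent level N down to 1; within a
    row, cells are visited by ascending pool size (ties seeded). Each cell's
    budget is the remaining budget divided (floor) among the cells not yet
    examined in this pass, counting only cells that still held calls at
    pass start. Selected calls become invalid for later cells. Passes
    repeat while budget and selectable calls remain; if a pass with floor
    quotas selects nothing, a final pass grants one selection per non-empty
    cell in traversal order until the budget is spent.
    """
    rng = Random(seed)
    matrix = OverlapMatrix(profile)
    tiebreak = list(profile.callers)
    rng.shuffle(tiebreak)
    rank = {c: i for i, c in enumerate(tiebreak)}

    remaining = min(_as_n_targets(budget), len(profile))
    consumed: set[VariantKey] = set()
    chosen: list[VariantKey] = []
    attribution: dict[VariantKey, str] = {}

    def traversal() -> list[tuple[int, str]]:
        """Non-empty cells in traversal order, given current consumption."""
        cells: list[tuple[int, str]] = []
        for level in range(matrix.n_levels, 0, -1):
            row = [
                (len(matrix.cell(level, c) - consumed), rank[c], c)
                for c in matrix.callers
                if matrix.cell(level, c) - consumed
            ]
            row.sort()
            cells.extend((level, c) for _, _, c in row)
        return cells

    def take_from(level: int, caller: str, k: int) -> int:
        avail = sorted(matrix.cell(level, caller) - consumed)
        take = min(k, len(avail))
        if take == 0:
            return 0
        picks = avail if take == len(avail) else rng.sample(avail, take)
        for v in picks:
            attribution[v] = f"cell={level}:{caller}"
        chosen.extend(picks)
        consumed.update(picks)
        return take

    while remaining > 0:
        cells = traversal()
        if not cells:
            break
        unexamined = len(cells)
        spent = 0
        for level, caller in cells:
            if remaining == 0:
                break
            cell_budget = remaining // unexamined
            got = take_from(level, caller, cell_budget)
            remaining -= got
            spent += got
            unexamined -= 1
        if spent == 0:
            # floor quotas starved every cell: grant one per cell in order
            for level, caller in cells:
                if remaining == 0:
                    break
                got = take_from(level, caller, 1)
                remaining -= got
                spent += got
            if spent == 0:
                break
    return Selection(
        variants=tuple(chosen),
        attribution=attribution,
        strategy_name="directed_sampling",
        seed=seed,
    )


_STRATEGIES: dict[str, Callable[[CallProfile, Budget | int, int], Selection]] = {
    "random_rows": select_random_rows,
    "directed_sampling": select_directed_sampling,
    "equal_per_caller": select_equal_per_caller,
    "equal_per_overlap": select_equal_per_overlap,
    "increasing_with_overlap": select_increasing_with_overlap,
    "decreasing_with_overlap": select_decreasing_with_overlap,
}


def select(
    profile: CallProfile,
    budget: Budget | int,
    strategy: str | StrategyConfig,
    seed: int | None = None,
) -> Selection:
    """Run a selection strategy by name."""
    if isinstance(strategy, StrategyConfig):
        name = strategy.name
        seed = strategy.seed if seed is None else seed
    else:
        name = strategy
        seed = 0 if seed is None else seed
    try:
        fn = _STRATEGIES[name]
    except KeyError:
        raise ValueError(
            f"unknown strategy {name!r}; expected one of {STRATEGY_NAMES}"
        ) from None
    return fn(profile, budget, seed)
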