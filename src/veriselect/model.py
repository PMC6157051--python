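"""Core domain types for multi-caller variant call sets.

A verification study re-tests a subset of variant calls on an orthogonal
platform to estimate each caller's error profile. The objects here capture
the minimal structure that selection and evaluation need: which variants
exist, which callers predicted each one (the *overlap level* of a variant
is the number of callers that made it), and which variants are real.

Variants are keyed by (chromosome, 1-based position) only; alleles and
genotypes are outside the data model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence


class VariantKey(NamedTuple):
    """A variant identified by chromosome label and 1-based position."""

    chrom: str
    pos: int


def _check_key(key: VariantKey) -> VariantKey:
    if key.pos < 1:
        raise ValueError(f"position must be >= 1, got {key.pos!r} on {key.chrom!r}")
    return key


class CallProfile:
    """The union of variants called by an ensemble of callers.

    Parameters
    ----------
    callers
        Ordered, distinct caller identifiers (length N >= 1).
    membership
        Mapping from :class:`VariantKey` to the non-empty set of callers
        that predicted it. Every member must be one of ``callers``.
    """

    def __init__(
        self,
        callers: Sequence[str],
        membership: Mapping[VariantKey, Iterable[str]],
    ) -> None:
        self.callers: tuple[str, ...] = tuple(callers)
        if len(self.callers) == 0:
            raise ValueError("a call profile needs at least one caller")
        if len(set(self.callers)) != len(self.callers):
            raise ValueError("caller identifiers must be distinct")
        caller_set = set(self.callers)
        mem: dict[VariantKey, frozenset[str]] = {}
        for key, group in membership.items():
            key = _check_key(VariantKey(*key))
            g = frozenset(group)
            if not g:
                raise ValueError(f"variant {key} has an empty caller set")
            if not g <= caller_set:
                raise ValueError(
                    f"variant {key} names unknown callers: {sorted(g - caller_set)}"
                )
            mem[key] = g
        self.membership: dict[VariantKey, frozenset[str]] = mem
        # per-caller call sets, in deterministic (sorted) variant order
        self._caller_calls: dict[str, tuple[VariantKey, ...]] = {
            c: tuple(sorted(v for v, g in mem.items() if c in g)) for c in self.callers
        }

    # -- basic accessors -------------------------------------------------

    @property
    def n_callers(self) -> int:
        return len(self.callers)

    @property
    def variants(self) -> tuple[VariantKey, ...]:
        """All variants in the union, sorted by (chrom, pos)."""
        return tuple(sorted(self.membership))

    def __len__(self) -> int:
        return len(self.membership)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.membership

    def __iter__(self) -> Iterator[VariantKey]:
        return iter(sorted(self.membership))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CallProfile):
            return NotImplemented
        return self.callers == other.callers and self.membership == other.membership

    def overlap_level(self, key: VariantKey) -> int:
        """Number of callers that predicted ``key`` (1..N)."""
        return len(self.membership[key])

    def calls_of(self, caller: str) -> tuple[VariantKey, ...]:
        """All variants predicted by ``caller``, sorted."""
        return self._caller_calls[caller]

    def level_counts(self, caller: str) -> dict[int, int]:
        """Caller's total call count at each overlap level it occupies."""
        counts: dict[int, int] = {}
        for v in self._caller_calls[caller]:
            k = len(self.membership[v])
            counts[k] = counts.get(k, 0) + 1
        return counts

    def variants_at_level(self, level: int) -> tuple[VariantKey, ...]:
        return tuple(
            sorted(v for v, g in self.membership.items() if len(g) == level)
        )

    def restrict(self, callers: Sequence[str]) -> "CallProfile":
        """Profile restricted to a caller subset.

        Variants no longer predicted by any surviving caller are dropped;
        overlap levels are recomputed within the subset.
        """
        keep = [c for c in self.callers if c in set(callers)]
        if not keep:
            raise ValueError("restriction leaves no callers")
        keep_set = set(keep)
        mem = {
            v: g & keep_set for v, g in self.membership.items() if g & keep_set
        }
        return CallProfile(keep, mem)


class TruthTable:
    """Mapping from variants to a boolean truth label.

    Looking up an unlabelled variant raises ``KeyError``: the evaluation
    contract requires every selected call to carry a verification result,
    and a silent default would corrupt the confusion counts.
    """

    def __init__(self, labels: Mapping[VariantKey, bool]) -> None:
        self.labels: dict[VariantKey, bool] = {
            _check_key(VariantKey(*k)): bool(v) for k, v in labels.items()
        }

    def __getitem__(self, key: VariantKey) -> bool:
        try:
            return self.labels[key]
        except KeyError:
            raise KeyError(
                f"variant {key} has no truth label; every selected call must be labelled"
            ) from None

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.labels

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TruthTable):
            return NotImplemented
        return self.labels == other.labels

    @property
    def n_true(self) -> int:
        return sum(self.labels.values())

    @property
    def true_variants(self) -> tuple[VariantKey, ...]:
        return tuple(sorted(v for v, t in self.labels.items() if t))


@dataclass(frozen=True)
class Budget:
    """Number of verification candidates that may be selected."""

    n_targets: int

    def __post_init__(self) -> None:
        if self.n_targets < 1:
            raise ValueError(f"budget must be >= 1, got {self.n_targets}")


@dataclass(frozen=True)
class Selection:
    """The outcome of one selection strategy run.

    ``attribution`` records, for diagnostics, which caller / overlap level /
    matrix cell consumed each variant from its allocation; every attributed
    caller actually predicted the variant.
    """

    variants: tuple[VariantKey, ...]
    attribution: Mapping[VariantKey, str]
    strategy_name: str
    seed: int

    def __post_init__(self) -> None:
        if len(set(self.variants)) != len(self.variants):
            raise ValueError("selection contains duplicate variants")

    def __len__(self) -> int:
        return len(self.variants)


class OverlapMatrix:
    """The call overlap-by-caller matrix.

    Row k (k = 1..N) holds the calls with overlap level exactly k; column j
    holds the calls of caller j. ``cell(k, j)`` is their intersection, so a
    level-k variant appears in exactly k cells, all in row k. Row 1 cells
    are pairwise disjoint (unique calls); the union of all cells is the
    full variant union.
    """

    def __init__(self, profile: CallProfile) -> None:
        self.callers = profile.callers
        self.n_levels = profile.n_callers
        cells: dict[tuple[int, str], set[VariantKey]] = {
            (k, j): set()
            for k in range(1, self.n_levels + 1)
            for j in self.callers
        }
        for v, group in profile.membership.items():
            k = len(group)
            for j in group:
                cells[(k, j)].add(v)
        self.cells: dict[tuple[int, str], frozenset[VariantKey]] = {
            key: frozenset(s) for key, s in cells.items()
        }

    def cell(self, level: int, caller: str) -> frozenset[VariantKey]:
        return self.cells[(level, caller)]


def build_call_profile(
    records: Iterable[tuple[str, VariantKey]],
    callers: Sequence[str] | None = None,
) -> CallProfile:
    """Build a :class:`CallProfile` from (caller, variant) records.

    Duplicate (caller, variant) pairs collapse to one. If ``callers`` is
    omitted the caller list is the sorted set of ids seen in the records.
    """
    membership: dict[VariantKey, set[str]] = {}
    seen: set[str] = set()
    n = 0
    for caller, key in records:
        n += 1
        seen.add(caller)
        membership.setdefault(VariantKey(*key), set()).add(caller)
    if n == 0:
        raise ValueError("no calls: cannot build a profile from an empty record set")
    if callers is None:
        callers = sorted(seen)
    return CallProfile(callers, membership)


def build_overlap_matrix(profile: CallProfile) -> OverlapMatrix:
    """Construct the overlap-by-caller matrix for a profile."""
    return OverlapMatrix(profile)
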