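"""Shared fixtures and independent oracle helpers.

The enumeration and brute-force helpers here are deliberately naive and
separate from the package's own code paths: they re-derive expected
values from first principles so the tests do not just mirror the
implementation.
"""

from __future__ import annotations

from itertools import combinations_with_replacement
from typing import Iterator, Sequence

import pytest

from veriselect.model import CallProfile, TruthTable, VariantKey


def vk(pos: int, chrom: str = "chr1") -> VariantKey:
    return VariantKey(chrom, pos)


def profile_from_groups(groups: Sequence[Sequence[str]]) -> CallProfile:
    """Profile with variants chr1:1..m whose caller sets are ``groups``."""
    callers = sorted({c for g in groups for c in g})
    return CallProfile(
        callers, {vk(i + 1): set(g) for i, g in enumerate(groups)}
    )


def enumerate_profiles(
    n_callers: int, max_variants: int, min_variants: int = 1
) -> Iterator[CallProfile]:
    """Every canonical profile with exactly ``n_callers`` callers.

    Profiles are canonical up to variant relabelling: a profile is a
    multiset of non-empty caller subsets, enumerated by combinations with
    repetition. All callers are present in the caller list even if some
    make no calls... except the CallProfile contract requires nothing of
    idle callers, so profiles where a caller makes zero calls are included.
    """
    callers = [chr(ord("A") + i) for i in range(n_callers)]
    subsets: list[tuple[str, ...]] = []
    for size in range(1, n_callers + 1):
        from itertools import combinations

        subsets.extend(combinations(callers, size))
    for m in range(min_variants, max_variants + 1):
        for combo in combinations_with_replacement(subsets, m):
            yield CallProfile(
                callers, {vk(i + 1): set(g) for i, g in enumerate(combo)}
            )


def brute_force_confusion(caller, profile, selected_variants, truth):
    """Naive reference classification of a selection for one caller."""
    calls = set(profile.calls_of(caller))
    sel = set(selected_variants)
    trues = {v for v in sel if truth[v]}
    tp = len(sel & calls & trues)
    fp = len((sel & calls) - trues)
    fn = len(trues - calls)
    return tp, fp, fn


@pytest.fixture
def two_caller_profile() -> CallProfile:
    """A: unique {1,2}; B: unique {3}; shared {4,5}."""
    return profile_from_groups([("A",), ("A",), ("B",), ("A", "B"), ("A", "B")])


@pytest.fixture
def three_level_profile() -> CallProfile:
    """3 callers with 10 variants at each overlap level 1, 2 and 3."""
    groups = [("A",)] * 4 + [("B",)] * 3 + [("C",)] * 3
    groups += [("A", "B")] * 5 + [("B", "C")] * 5
    groups += [("A", "B", "C")] * 10
    return profile_from_groups(groups)


@pytest.fixture
def truth_all_true():
    def make(profile: CallProfile) -> TruthTable:
        return TruthTable({v: True for v in profile.variants})

    return make
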