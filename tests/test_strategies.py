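"""Selection strategies: quotas, redistribution, and the budget contract."""

import math
from collections import Counter
from fractions import Fraction
from random import Random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from veriselect.model import CallProfile
from veriselect.strategies import (
    STRATEGY_NAMES,
    StrategyConfig,
    apportion,
    select,
    select_decreasing_with_overlap,
    select_directed_sampling,
    select_equal_per_caller,
    select_equal_per_overlap,
    select_increasing_with_overlap,
    select_random_rows,
)

from conftest import profile_from_groups, vk


def attribution_counts(selection) -> Counter:
    return Counter(selection.attribution[v] for v in selection.variants)


class TestApportion:
    def test_equal_weights_integral(self):
        assert apportion({"a": 1, "b": 1, "c": 1}, 9).quotas == {"a": 3, "b": 3, "c": 3}

    def test_proportional_integral(self):
        assert apportion({"a": 1, "b": 2, "c": 3}, 12).quotas == {"a": 2, "b": 4, "c": 6}

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            apportion({"a": 0, "b": 0}, 5)

    @given(
        weights=st.lists(st.integers(1, 7), min_size=1, max_size=5),
        total=st.integers(0, 30),
        seed=st.integers(0, 10),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_largest_remainder_oracle(self, weights, total, seed):
        """Quotas sum to the total and match a Fraction-exact
        largest-remainder allocation: every unit gets floor(share) or
        floor(share)+1, and no unit with a larger fractional part is
        passed over in favour of a strictly smaller one."""
        keyed = {f"u{i}": w for i, w in enumerate(weights)}
        plan = apportion(keyed, total, seed)
        assert sum(plan.quotas.values()) == total
        wsum = sum(weights)
        share = {k: Fraction(total * w, wsum) for k, w in keyed.items()}
        frac = {k: share[k] - math.floor(share[k]) for k in keyed}
        for k, q in plan.quotas.items():
            assert q in (math.floor(share[k]), math.floor(share[k]) + 1)
        bumped = {k for k, q in plan.quotas.items() if q == math.floor(share[k]) + 1}
        for b in bumped:
            for k in set(keyed) - bumped:
                assert frac[b] >= frac[k]


class TestRandomRows:
    def test_without_replacement_cardinality(self):
        p = profile_from_groups([("A",)] * 10)
        sel = select_random_rows(p, 4, seed=0)
        assert len(sel) == 4 and len(set(sel.variants)) == 4

    def test_exhaustion_returns_everything(self):
        p = profile_from_groups([("A",)] * 10)
        assert len(select_random_rows(p, 25, seed=0)) == 10

    def test_uniformity_against_hypergeometric(self):
        """Budget 3 of 6 variants: each variant's inclusion frequency over
        2000 seeds should be 1/2 within 3 sigma of the binomial error."""
        p = profile_from_groups([("A",), ("A",), ("B",), ("B",), ("A", "B"), ("B",)])
        n_seeds = 2000
        freq = Counter()
        for s in range(n_seeds):
            freq.update(select_random_rows(p, 3, seed=s).variants)
        sigma = math.sqrt(0.5 * 0.5 / n_seeds)
        for v in p.variants:
            assert abs(freq[v] / n_seeds - 0.5) < 3 * sigma

    def test_attributed_caller_made_the_call(self):
        p = profile_from_groups([("A",), ("B",), ("A", "B")] * 3)
        sel = select_random_rows(p, 6, seed=3)
        for v in sel.variants:
            assert sel.attribution[v] in p.membership[v]


class TestEqualPerCaller:
    def test_exact_division_disjoint_pools(self):
        groups = [("A",)] * 10 + [("B",)] * 10 + [("C",)] * 10
        sel = select_equal_per_caller(profile_from_groups(groups), 9, seed=1)
        assert attribution_counts(sel) == {"A": 3, "B": 3, "C": 3}

    @pytest.mark.parametrize("seed", range(10))
    def test_shortfall_redistributes_equally(self, seed):
        """Pools of 10, 10 and 1: the starved caller contributes its one
        call and its unspent quota splits equally over the other two."""
        groups = [("A",)] * 10 + [("B",)] * 10 + [("C",)]
        sel = select_equal_per_caller(profile_from_groups(groups), 9, seed=seed)
        counts = attribution_counts(sel)
        assert counts["C"] == 1 and sorted(counts.values()) == [1, 4, 4]

    def test_shared_calls_invalidated_across_callers(self):
        groups = [("A", "B")] * 6
        sel = select_equal_per_caller(profile_from_groups(groups), 4, seed=2)
        assert len(sel) == 4
        assert attribution_counts(sel) == {"A": 2, "B": 2}


class TestOverlapFamily:
    def test_equal_per_overlap_exact_division(self):
        groups = [("A",)] * 10 + [("A", "B")] * 10 + [("A", "B", "C")] * 10
        sel = select_equal_per_overlap(profile_from_groups(groups), 9, seed=0)
        counts = attribution_counts(sel)
        assert counts == {"level=1": 3, "level=2": 3, "level=3": 3}

    @pytest.mark.parametrize("seed", range(10))
    def test_empty_level_budget_redistributed(self, seed):
        """N=3 but no level-3 calls: the 9-call budget lands 4/5 on levels
        1 and 2 (which of the two gets the extra is seed-dependent)."""
        groups = [("A",)] * 10 + [("A", "B")] * 10 + [("C",)] * 0
        p = CallProfile(["A", "B", "C"], {vk(i + 1): g for i, g in enumerate(
            [{"A"}] * 10 + [{"A", "B"}] * 10)})
        sel = select_equal_per_overlap(p, 9, seed=seed)
        counts = attribution_counts(sel)
        assert sorted(counts.values()) == [4, 5] and len(sel) == 9

    def test_all_unique_full_redistribution(self):
        p = profile_from_groups([("A",)] * 4 + [("B",)] * 4)
        sel = select_equal_per_overlap(p, 4, seed=0)
        assert attribution_counts(sel) == {"level=1": 4}

    def test_increasing_quotas_proportional_to_level(self, three_level_profile):
        sel = select_increasing_with_overlap(three_level_profile, 12, seed=0)
        counts = attribution_counts(sel)
        assert counts == {"level=1": 2, "level=2": 4, "level=3": 6}

    def test_increasing_two_levels_exact_thirds(self):
        groups = [("A",)] * 10 + [("A", "B")] * 10
        sel = select_increasing_with_overlap(profile_from_groups(groups), 9, seed=0)
        assert attribution_counts(sel) == {"level=1": 3, "level=2": 6}

    @pytest.mark.parametrize("seed", range(5))
    def test_increasing_largest_remainder_budget_10(self, three_level_profile, seed):
        sel = select_increasing_with_overlap(three_level_profile, 10, seed=seed)
        counts = attribution_counts(sel)
        assert sum(counts.values()) == 10
        for k in (1, 2, 3):
            assert abs(counts[f"level={k}"] - 10 * k / 6) < 1 + 1e-9

    def test_decreasing_exact_split(self, three_level_profile):
        sel = select_decreasing_with_overlap(three_level_profile, 11, seed=0)
        counts = attribution_counts(sel)
        assert counts == {"level=1": 6, "level=2": 3, "level=3": 2}

    def test_decreasing_two_levels(self):
        groups = [("A",)] * 10 + [("A", "B")] * 10
        sel = select_decreasing_with_overlap(profile_from_groups(groups), 9, seed=0)
        assert attribution_counts(sel) == {"level=1": 6, "level=2": 3}

    @pytest.mark.parametrize("seed", range(5))
    def test_decreasing_largest_remainder_four_levels(self, seed):
        groups = (
            [("A",)] * 15
            + [("A", "B")] * 15
            + [("A", "B", "C")] * 15
            + [("A", "B", "C", "D")] * 15
        )
        sel = select_decreasing_with_overlap(profile_from_groups(groups), 25, seed=seed)
        counts = attribution_counts(sel)
        assert sum(counts.values()) == 25
        wsum = sum(1 / k for k in range(1, 5))
        for k in range(1, 5):
            assert abs(counts[f"level={k}"] - 25 * (1 / k) / wsum) < 1 + 1e-9

    def test_proportionality_limit(self):
        """With ample calls at every level, increasing-with-overlap quota
        ratios approach k : k' at a large budget."""
        groups = (
            [("A",)] * 6000 + [("A", "B")] * 6000 + [("A", "B", "C")] * 6000
        )
        sel = select_increasing_with_overlap(profile_from_groups(groups), 10_000, seed=0)
        counts = attribution_counts(sel)
        for k in (1, 2, 3):
            assert counts[f"level={k}"] == pytest.approx(10_000 * k / 6, abs=1)


class TestDirectedSampling:
    @pytest.mark.parametrize("seed", range(20))
    def test_hand_worked_two_caller_example(self, seed):
        """A-unique {a1,a2}, B-unique {b1}, shared {s1,s2}, budget 4: one
        shared call from each level-2 cell (the second cell's pool having
        shrunk by invalidation), b1, and one A-unique call."""
        p = CallProfile(
            ["A", "B"],
            {
                vk(1): {"A"},
                vk(2): {"A"},
                vk(3): {"B"},
                vk(4): {"A", "B"},
                vk(5): {"A", "B"},
            },
        )
        sel = select_directed_sampling(p, 4, seed=seed)
        chosen = set(sel.variants)
        assert len(chosen) == 4
        assert {vk(4), vk(5)} <= chosen  # both shared variants
        assert vk(3) in chosen  # B's only unique call
        assert len(chosen & {vk(1), vk(2)}) == 1

    def test_budget_exhaustion_selects_everything(self, two_caller_profile):
        sel = select_directed_sampling(two_caller_profile, 100, seed=0)
        assert set(sel.variants) == set(two_caller_profile.variants)

    def test_single_caller_degenerate(self):
        p = profile_from_groups([("A",)] * 5)
        sel = select_directed_sampling(p, 3, seed=0)
        assert len(sel) == 3
        assert all(a == "cell=1:A" for a in sel.attribution.values())

    @pytest.mark.parametrize("seed", range(10))
    def test_cell_coverage_when_budget_allows(self, seed):
        """With budget >= number of non-empty cells, every originally
        non-empty cell sees at least one of its variants selected."""
        rng = Random(seed)
        groups = [
            tuple(rng.sample("ABC", rng.randint(1, 3))) for _ in range(12)
        ]
        p = profile_from_groups(groups)
        from veriselect.model import build_overlap_matrix

        m = build_overlap_matrix(p)
        nonempty = {key: cell for key, cell in m.cells.items() if cell}
        sel = select_directed_sampling(p, len(nonempty), seed=seed)
        chosen = set(sel.variants)
        for key, cell in nonempty.items():
            assert cell & chosen, f"cell {key} has no selected variant"


class TestSharedContract:
    @pytest.mark.parametrize("name", STRATEGY_NAMES)
    def test_determinism(self, name, three_level_profile):
        a = select(three_level_profile, 13, name, seed=42)
        b = select(three_level_profile, 13, name, seed=42)
        assert a == b

    @pytest.mark.parametrize("name", STRATEGY_NAMES)
    def test_budget_conservation_randomized(self, name):
        """|selection| = min(budget, |union|) on random profiles, and no
        variant appears twice."""
        rng = Random(1234)
        for _ in range(40):
            n_callers = rng.randint(1, 4)
            callers = [chr(ord("A") + i) for i in range(n_callers)]
            m = rng.randint(1, 12)
            groups = [
                tuple(rng.sample(callers, rng.randint(1, n_callers)))
                for _ in range(m)
            ]
            p = profile_from_groups(groups)
            budget = rng.randint(1, 15)
            sel = select(p, budget, name, seed=rng.randint(0, 10**6))
            assert len(sel) == min(budget, len(p))
            assert len(set(sel.variants)) == len(sel.variants)
            for v in sel.variants:
                assert v in p.membership

    def test_single_caller_distributional_equivalence(self):
        """With N=1 every strategy reduces to uniform sampling without
        replacement: per-variant inclusion frequencies agree across
        strategies within 3 sigma."""
        p = profile_from_groups([("A",)] * 8)
        n_seeds, budget = 600, 3
        sigma = math.sqrt((budget / 8) * (1 - budget / 8) / n_seeds)
        freqs = {}
        for name in STRATEGY_NAMES:
            c = Counter()
            for s in range(n_seeds):
                c.update(select(p, budget, name, seed=s).variants)
            freqs[name] = {v: c[v] / n_seeds for v in p.variants}
        for name in STRATEGY_NAMES:
            for v in p.variants:
                assert abs(freqs[name][v] - budget / 8) < 4 * sigma

    def test_unknown_strategy_rejected(self, two_caller_profile):
        with pytest.raises(ValueError, match="unknown strategy"):
            select(two_caller_profile, 2, "nonesuch")
        with pytest.raises(ValueError, match="unknown strategy"):
            StrategyConfig("nonesuch")
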