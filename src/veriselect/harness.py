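"""Benchmarking harness: strategy x budget x caller-subset sweeps.

A sweep measures how well each selection strategy's subset-based F1
estimate tracks the full-set ("true") F1, across verification budgets,
caller subsets and replicate runs. The per-row quantity is
DF1 = subset F1 - full F1; a strategy is good when its DF1 values sit
tightly around zero. Rows whose subset score is N/A are flagged and
excluded from location/spread statistics, but their rate is reported —
losing a caller entirely is itself a failure mode worth seeing.

Strategies are ranked by the median of |DF1| (ascending), ties broken by
IQR and then name. Every row's seed derives deterministically from the
master seed and the row's factor coordinates, so any single experiment
can be reproduced in isolation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from random import Random
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluation import evaluate_all_callers, f1_difference, full_set_metrics
from .model import CallProfile, TruthTable
from .strategies import STRATEGY_NAMES, select

SUBSET_MODES: tuple[str, ...] = (
    "complete",
    "best_per_team",
    "random_k_of_best",
    "random_k_of_all",
)

DEFAULT_BUDGETS: tuple[int, ...] = (100, 250, 500, 1000, 2500)


def derive_seed(master_seed: int, *coords: object) -> int:
    """Stable sub-seed from the master seed and factor coordinates."""
    tag = ":".join([str(master_seed), *map(str, coords)])
    digest = hashlib.blake2b(tag.encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass(frozen=True)
class SweepConfig:
    """Full factorial design of one benchmarking sweep."""

    budgets: tuple[int, ...] = DEFAULT_BUDGETS
    strategies: tuple[str, ...] = STRATEGY_NAMES
    subset_modes: tuple[str, ...] = ("complete",)
    subset_k: int = 3
    n_subset_replicates: int = 10
    n_strategy_replicates: int = 10
    modes: tuple[str, ...] = ("default", "weighted")
    baseline: str = "all-mutations"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.budgets or min(self.budgets) < 1:
            raise ValueError("budgets must be positive")
        unknown = set(self.strategies) - set(STRATEGY_NAMES)
        if unknown:
            raise ValueError(f"unknown strategies: {sorted(unknown)}")
        unknown = set(self.subset_modes) - set(SUBSET_MODES)
        if unknown:
            raise ValueError(f"unknown subset modes: {sorted(unknown)}")
        if self.n_subset_replicates < 1 or self.n_strategy_replicates < 1:
            raise ValueError("replicate counts must be positive")
        if self.subset_k < 1:
            raise ValueError("subset_k must be positive")


@dataclass
class SweepReport:
    """Raw per-(configuration x caller) rows plus the ranking summary."""

    rows: pd.DataFrame
    summary: pd.DataFrame


# -- caller subsetting ---------------------------------------------------


def best_callers_per_team(
    profile: CallProfile,
    truth: TruthTable,
    team_map: Mapping[str, str],
    baseline: str = "all-mutations",
) -> list[str]:
    """For each team, its submission with the highest full-set F1."""
    missing = [c for c in profile.callers if c not in team_map]
    if missing:
        raise ValueError(f"no team mapping for callers: {missing}")
    f1 = {
        r.caller: (-1.0 if r.f1 is None else r.f1)
        for r in full_set_metrics(profile, truth, baseline)
    }
    best: dict[str, str] = {}
    for caller in profile.callers:
        team = team_map[caller]
        if team not in best or f1[caller] > f1[best[team]]:
            best[team] = caller
    return [c for c in profile.callers if c in set(best.values())]


def subset_callers(
    profile: CallProfile,
    mode: str,
    k: int = 3,
    seed: int = 0,
    truth: TruthTable | None = None,
    team_map: Mapping[str, str] | None = None,
    baseline: str = "all-mutations",
) -> CallProfile:
    """Restrict a profile to one of the benchmark caller subsets.

    * ``complete`` — the profile unchanged;
    * ``best_per_team`` — each team's highest full-set-F1 submission
      (requires ``truth`` and an explicit caller -> team map);
    * ``random_k_of_best`` — k uniform draws from the best-per-team pool;
    * ``random_k_of_all`` — k uniform draws from all callers.
    """
    if mode == "complete":
        return profile
    if mode == "random_k_of_all":
        pool = list(profile.callers)
    elif mode in ("best_per_team", "random_k_of_best"):
        if truth is None or team_map is None:
            raise ValueError(f"mode {mode!r} requires truth and a caller->team map")
        pool = best_callers_per_team(profile, truth, team_map, baseline)
        if mode == "best_per_team":
            return profile.restrict(pool)
    else:
        raise ValueError(f"unknown subset mode {mode!r}")
    if k > len(pool):
        raise ValueError(f"subset_k={k} exceeds the {len(pool)} available callers")
    rng = Random(seed)
    return profile.restrict(rng.sample(pool, k))


# -- design enumeration --------------------------------------------------


def enumerate_caller_subsets(config: SweepConfig) -> list[tuple[str, int]]:
    """(subset mode, replicate index) pairs of the design.

    Deterministic modes contribute one subset each; random modes
    contribute ``n_subset_replicates`` each. The benchmark design with all
    four modes and 10 replicates gives 1 + 1 + 10 + 10 = 22 subsets.
    """
    pairs: list[tuple[str, int]] = []
    for mode in config.subset_modes:
        reps = 1 if mode in ("complete", "best_per_team") else config.n_subset_replicates
        pairs.extend((mode, r) for r in range(reps))
    return pairs


def enumerate_design(
    config: SweepConfig, dataset_ids: Sequence[str]
) -> list[tuple[str, str, int, int]]:
    """All (dataset, subset mode, subset replicate, budget) configurations.

    One configuration is one comparison unit: every strategy runs on each.
    """
    return [
        (ds, mode, rep, budget)
        for ds in dataset_ids
        for mode, rep in enumerate_caller_subsets(config)
        for budget in config.budgets
    ]


# -- experiments ---------------------------------------------------------

_ROW_COLUMNS = [
    "dataset",
    "subset_mode",
    "subset_replicate",
    "strategy",
    "mode",
    "budget",
    "strategy_replicate",
    "seed",
    "caller",
    "subset_f1",
    "full_f1",
    "delta_f1",
    "na",
]


def run_experiment(
    profile: CallProfile,
    truth: TruthTable,
    strategy: str,
    budget: int,
    mode: str,
    seed: int,
    baseline: str = "all-mutations",
    full_records: Sequence | None = None,
) -> list[dict]:
    """One selection -> evaluation -> per-caller DF1 pass."""
    if full_records is None:
        full_records = full_set_metrics(profile, truth, baseline)
    selection = select(profile, budget, strategy, seed)
    subset_records = evaluate_all_callers(profile, selection, truth, mode)
    rows = []
    for sub, full in zip(subset_records, full_records):
        delta = f1_difference(sub, full)
        rows.append(
            {
                "strategy": strategy,
                "mode": mode,
                "budget": budget,
                "seed": seed,
                "caller": sub.caller,
                "subset_f1": np.nan if sub.f1 is None else sub.f1,
                "full_f1": np.nan if full.f1 is None else full.f1,
                "delta_f1": np.nan if delta is None else delta,
                "na": delta is None,
            }
        )
    return rows


def run_sweep(
    config: SweepConfig,
    datasets: Mapping[str, tuple[CallProfile, TruthTable]],
    team_map: Mapping[str, str] | None = None,
) -> SweepReport:
    """Run the full factorial sweep over all datasets.

    ``datasets`` maps a dataset id to its (profile, truth) pair. Every
    row's seed is ``derive_seed(master_seed, dataset, subset coordinates,
    strategy, mode, budget, replicate)``, so replicates are independent
    but individually reproducible.
    """
    all_rows: list[dict] = []
    for ds, mode_rep_budget in _group_design(config, datasets):
        profile, truth = datasets[ds]
        for subset_mode, subset_rep, budget_list in mode_rep_budget:
            sub_profile = subset_callers(
                profile,
                subset_mode,
                k=config.subset_k,
                seed=derive_seed(config.master_seed, ds, subset_mode, subset_rep),
                truth=truth,
                team_map=team_map,
                baseline=config.baseline,
            )
            full_records = full_set_metrics(sub_profile, truth, config.baseline)
            for budget in budget_list:
                for strategy in config.strategies:
                    for mode in config.modes:
                        for rep in range(config.n_strategy_replicates):
                            seed = derive_seed(
                                config.master_seed,
                                ds,
                                subset_mode,
                                subset_rep,
                                strategy,
                                mode,
                                budget,
                                rep,
                            )
                            for row in run_experiment(
                                sub_profile,
                                truth,
                                strategy,
                                budget,
                                mode,
                                seed,
                                config.baseline,
                                full_records,
                            ):
                                row.update(
                                    dataset=ds,
                                    subset_mode=subset_mode,
                                    subset_replicate=subset_rep,
                                    strategy_replicate=rep,
                                )
                                all_rows.append(row)
    rows = pd.DataFrame(all_rows, columns=_ROW_COLUMNS)
    return SweepReport(rows=rows, summary=rank_strategies(rows))


def _group_design(
    config: SweepConfig, datasets: Mapping[str, object]
) -> Iterable[tuple[str, list[tuple[str, int, tuple[int, ...]]]]]:
    """Design grouped so each caller subset is built and scored once."""
    for ds in datasets:
        yield ds, [
            (mode, rep, config.budgets)
            for mode, rep in enumerate_caller_subsets(config)
        ]


def rank_strategies(rows: pd.DataFrame) -> pd.DataFrame:
    """Per (strategy, mode) summary, ranked by median |DF1|.

    N/A rows are excluded from location and spread statistics; their rate
    is a separate column. A strategy/mode with no defined DF1 at all is
    ranked last and flagged. Ties on the median break by IQR, then name.
    """
    summaries = []
    for (strategy, mode), grp in rows.groupby(["strategy", "mode"], sort=True):
        delta = grp["delta_f1"].dropna()
        na_rate = float(grp["na"].mean()) if len(grp) else 0.0
        if delta.empty:
            summaries.append(
                {
                    "strategy": strategy,
                    "mode": mode,
                    "n": 0,
                    "median_delta_f1": np.nan,
                    "median_abs_delta_f1": np.nan,
                    "mean_abs_delta_f1": np.nan,
                    "iqr_abs_delta_f1": np.nan,
                    "na_rate": na_rate,
                    "all_na": True,
                }
            )
            continue
        abs_delta = delta.abs()
        q1, q3 = abs_delta.quantile([0.25, 0.75])
        summaries.append(
            {
                "strategy": strategy,
                "mode": mode,
                "n": int(len(delta)),
                "median_delta_f1": float(delta.median()),
                "median_abs_delta_f1": float(abs_delta.median()),
                "mean_abs_delta_f1": float(abs_delta.mean()),
                "iqr_abs_delta_f1": float(q3 - q1),
                "na_rate": na_rate,
                "all_na": False,
            }
        )
    summary = pd.DataFrame(summaries)
    if summary.empty:
        summary["rank"] = pd.Series(dtype=int)
        return summary
    order = summary.sort_values(
        by=["all_na", "median_abs_delta_f1", "iqr_abs_delta_f1", "strategy", "mode"],
        na_position="last",
        kind="mergesort",
    ).index
    summary.loc[order, "rank"] = np.arange(1, len(summary) + 1)
    summary["rank"] = summary["rank"].astype(int)
    return summary.sort_values("rank").reset_index(drop=True)
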