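"""Synthetic multi-caller call ensembles with fully known truth.

Real verification-study inputs are ensembles of somatic SNV call sets,
each caller with its own sensitivity and false-discovery profile, with
recurrent (shared) false positives from common error modes, and often with
highly skewed call-set sizes. The generator reproduces exactly those
statistical features — the only ones the selection and evaluation
machinery is sensitive to — over a single abstract chromosome:

* each caller detects every true mutation independently with its own
  sensitivity;
* each caller adds a fixed number of false positives, a configurable
  fraction of which are drawn from a common recurrent-error pool (creating
  false calls at overlap level >= 2), the rest from a private pool;
* true-mutation, pool and private-FP coordinates are drawn from disjoint
  slices of one global position draw, so a position's truth label is
  always unambiguous.

Sequence-level realism (read simulation, alleles, trinucleotide context)
is out of scope. Generation is a pure function of the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from random import Random
from typing import Sequence

from .model import CallProfile, TruthTable, VariantKey

_CHROM = "chr1"


@dataclass(frozen=True)
class CallerSpec:
    """One simulated caller: detection sensitivity and FP load."""

    name: str
    sensitivity: float
    n_false_positives: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValueError(f"sensitivity must be in [0,1], got {self.sensitivity}")
        if self.n_false_positives < 0:
            raise ValueError("n_false_positives must be >= 0")


def _default_callers() -> tuple[CallerSpec, ...]:
    # a strong, a mid and a noisy caller — enough spread that strategy
    # differences are visible without being adversarial
    return (
        CallerSpec("caller_A", sensitivity=0.95, n_false_positives=1500),
        CallerSpec("caller_B", sensitivity=0.85, n_false_positives=1000),
        CallerSpec("caller_C", sensitivity=0.75, n_false_positives=500),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic ensemble.

    ``shared_fp_fraction`` of each caller's false positives are drawn from
    a common pool of ``fp_pool_size`` recurrent-error positions; the rest
    are private to the caller. The default ensemble (3 callers, 6000 true
    mutations, ~10^4 distinct calls) is the desk-scale stand-in for a
    whole-genome multi-caller submission set.
    """

    genome_length: int = 10_000_000
    n_true: int = 6000
    callers: tuple[CallerSpec, ...] = field(default_factory=_default_callers)
    shared_fp_fraction: float = 0.3
    fp_pool_size: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true < 0:
            raise ValueError("n_true must be >= 0")
        if not 0.0 <= self.shared_fp_fraction <= 1.0:
            raise ValueError("shared_fp_fraction must be in [0,1]")
        if self.fp_pool_size < 0:
            raise ValueError("fp_pool_size must be >= 0")
        needed = self.n_true + self.fp_pool_size + sum(
            self._n_private(c) for c in self.callers
        )
        if needed > self.genome_length:
            raise ValueError(
                f"coordinate space too small: need {needed} distinct positions "
                f"but genome_length is {self.genome_length}"
            )
        for c in self.callers:
            if self._n_shared(c) > self.fp_pool_size:
                raise ValueError(
                    f"{c.name}: {self._n_shared(c)} shared FPs exceed the "
                    f"pool size {self.fp_pool_size}"
                )

    def _n_shared(self, c: CallerSpec) -> int:
        return round(self.shared_fp_fraction * c.n_false_positives)

    def _n_private(self, c: CallerSpec) -> int:
        return c.n_false_positives - self._n_shared(c)


def _draw_positions(config: SimulationConfig) -> tuple[
    list[int], list[int], dict[str, list[int]]
]:
    """One global draw of distinct positions, sliced into disjoint roles."""
    rng = Random(f"positions:{config.seed}")
    privates = {c.name: config._n_private(c) for c in config.callers}
    total = config.n_true + config.fp_pool_size + sum(privates.values())
    draw = rng.sample(range(1, config.genome_length + 1), total)
    true_pos = draw[: config.n_true]
    pool = draw[config.n_true : config.n_true + config.fp_pool_size]
    offset = config.n_true + config.fp_pool_size
    private: dict[str, list[int]] = {}
    for c in config.callers:
        private[c.name] = draw[offset : offset + privates[c.name]]
        offset += privates[c.name]
    return true_pos, pool, private


def simulate_truth(config: SimulationConfig) -> TruthTable:
    """The ground-truth mutation set: n_true distinct positions, all true."""
    true_pos, _, _ = _draw_positions(config)
    return TruthTable({VariantKey(_CHROM, p): True for p in true_pos})


def simulate_callers(config: SimulationConfig, truth: TruthTable) -> CallProfile:
    """Simulate every caller's call set over the given truth.

    Caller k detects each true mutation independently with probability
    ``sensitivity_k`` and adds its false positives (shared-pool draws may
    coincide across callers, producing recurrent FPs). ``truth`` must be
    the table produced by :func:`simulate_truth` for the same config.
    """
    true_pos, pool, private = _draw_positions(config)
    if set(truth.labels) != {VariantKey(_CHROM, p) for p in true_pos}:
        raise ValueError("truth table does not match this configuration/seed")
    membership: dict[VariantKey, set[str]] = {}

    def add(name: str, pos: int) -> None:
        membership.setdefault(VariantKey(_CHROM, pos), set()).add(name)

    for c in config.callers:
        rng = Random(f"caller:{c.name}:{config.seed}")
        for p in true_pos:
            if rng.random() < c.sensitivity:
                add(c.name, p)
        n_shared = config._n_shared(c)
        if n_shared:
            for p in rng.sample(pool, n_shared):
                add(c.name, p)
        for p in private[c.name]:
            add(c.name, p)
    if not membership:
        raise ValueError(
            "simulation produced no calls (all sensitivities and FP counts zero?)"
        )
    return CallProfile([c.name for c in config.callers], membership)


def simulate_ensemble(config: SimulationConfig) -> tuple[CallProfile, TruthTable]:
    """Convenience: (profile, truth) for one configuration.

    The returned truth table labels every call in the profile (false
    positives as 0) *and* every true mutation, detected or not, so it can
    drive both evaluation baselines directly.
    """
    truth = simulate_truth(config)
    profile = simulate_callers(config, truth)
    return profile, extend_truth_over_profile(profile, truth)


def extend_truth_over_profile(profile: CallProfile, truth: TruthTable) -> TruthTable:
    """Label every profile variant: true if in the truth set, else false.

    The generator's truth table lists true mutations only; evaluation needs
    a label for every call, so calls outside the truth set are false.
    """
    labels = {v: (v in truth and truth[v]) for v in profile.variants}
    labels.update(truth.labels)
    return TruthTable(labels)


def submission_pool_config(
    n_callers: int = 15,
    n_true: int = 5000,
    sensitivity_range: tuple[float, float] = (0.75, 0.95),
    fp_range: tuple[int, int] = (100, 600),
    shared_fp_fraction: float = 0.3,
    fp_pool_size: int = 1500,
    genome_length: int = 10_000_000,
    seed: int = 0,
) -> SimulationConfig:
    """A submission pool with a wide quality range, like a benchmarking
    challenge's call-set collection.

    Callers span the sensitivity and FP ranges on an even ladder (the
    weakest caller is also the noisiest), giving roughly 10^4 distinct
    calls at the defaults. This is the study ensemble for estimator
    calibration: per-caller biases of the overlap-stratified strategies
    are averaged over enough callers and levels to be informative without
    being dominated by any single caller's idiosyncrasy.
    """
    if n_callers < 2:
        raise ValueError("a submission pool needs at least 2 callers")
    s_lo, s_hi = sensitivity_range
    fp_lo, fp_hi = fp_range
    callers = tuple(
        CallerSpec(
            f"c{i:02d}",
            sensitivity=s_lo + (s_hi - s_lo) * i / (n_callers - 1),
            n_false_positives=fp_lo + int((fp_hi - fp_lo) * i / (n_callers - 1)),
        )
        for i in range(n_callers)
    )
    return SimulationConfig(
        genome_length=genome_length,
        n_true=n_true,
        callers=callers,
        shared_fp_fraction=shared_fp_fraction,
        fp_pool_size=fp_pool_size,
        seed=seed,
    )


def skewed_config(
    n_true: int = 2000,
    dominant_calls: int = 10_000,
    minor_calls: int = 10,
    n_minor: int = 2,
    genome_length: int = 10_000_000,
    seed: int = 0,
) -> SimulationConfig:
    """Configuration with one dominant caller and tiny minor call sets.

    The dominant caller detects everything and pads with private FPs to
    ``dominant_calls`` total; each minor caller makes about ``minor_calls``
    calls, half expected true, half false. This is the regime where
    uniform random sampling can select none of a minor caller's calls,
    leaving its scores N/A.
    """
    if dominant_calls < n_true:
        raise ValueError("dominant_calls must be >= n_true")
    minor_sens = min(1.0, (minor_calls / 2) / max(n_true, 1))
    callers = [
        CallerSpec("dominant", sensitivity=1.0,
                   n_false_positives=dominant_calls - n_true)
    ]
    for i in range(n_minor):
        callers.append(
            CallerSpec(
                f"minor_{i + 1}",
                sensitivity=minor_sens,
                n_false_positives=minor_calls - minor_calls // 2,
            )
        )
    return SimulationConfig(
        genome_length=genome_length,
        n_true=n_true,
        callers=tuple(callers),
        shared_fp_fraction=0.0,
        fp_pool_size=0,
        seed=seed,
    )


def skewed_ensemble(
    seed: int = 0, **overrides: int
) -> tuple[CallProfile, TruthTable]:
    """Generate the skewed (dominant + minor callers) ensemble."""
    return simulate_ensemble(skewed_config(seed=seed, **overrides))
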