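"""Generative model of the Gal80-balanced master-stock outcross.

The screen's cross produces F1 zygotes at a 1:1 sex ratio; every female
inherits the Gal4-inhibiting Gal80 X chromosome and develops normally, while
every male expresses the PAX7-FOXO1 transgene and survives to adulthood with
relative viability ``v`` (calibrated so that unmodified crosses yield 22%
males).  A heterozygous modifier multiplies male viability by ``m`` —
``m > 1`` for suppressors, ``m < 1`` for enhancers — with survival capped at
1.  Sampling is binomial at the clutch level:

    n_male_zygotes   ~ Binomial(clutch_n, 1/2)
    males            ~ Binomial(n_male_zygotes, min(1, v * m))
    females          ~ Binomial(clutch_n - n_male_zygotes, min(1, f))

The closed-form expected male fraction is ``s / (s + f')`` with
``s = min(1, v m)`` and ``f' = min(1, f)``; inverting it at the observed
baseline gives the calibration ``v = p / (1 - p)`` (0.28205 at p = 0.22).

Randomness is reproducible: a run is seeded once and each simulated line
draws from its own counter-derived stream, so per-line results are stable
under reordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .screen import (
    ENHANCER,
    NONMODIFIER,
    SUPPRESSOR,
    CrossTally,
    ScreenConfig,
    classify,
)

__all__ = [
    "SimConfig",
    "SimScreen",
    "PowerResult",
    "BASELINE_MALE_FRACTION",
    "expected_male_fraction",
    "calibrate_viability",
    "simulate_cross",
    "estimate_effect",
    "detection_power",
    "false_positive_rate",
    "generate_screen_table",
]

#: observed F1 male fraction of unmodified outcrosses of the master stock
BASELINE_MALE_FRACTION = 0.22


def calibrate_viability(p: float) -> float:
    """Baseline male viability ``v = p/(1-p)`` matching male fraction ``p``."""
    if not 0 <= p < 1:
        raise ValueError(f"male fraction must be in [0, 1), got {p}")
    return p / (1.0 - p)


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of one simulated cross.

    ``v``: baseline male relative viability (default calibrated to 22%);
    ``m``: modifier effect multiplier (1 = none); ``f``: female relative
    viability; ``clutch_n``: conceived F1 zygotes per line;
    ``poisson_clutch``: sample the clutch size Poisson(clutch_n) instead of
    fixing it, mirroring the spread of real cross sizes.
    """

    v: float = calibrate_viability(BASELINE_MALE_FRACTION)
    m: float = 1.0
    f: float = 1.0
    clutch_n: int = 300
    n_reps: int = 1000
    seed: int = 0
    poisson_clutch: bool = False

    def __post_init__(self) -> None:
        if self.v < 0 or self.m < 0 or self.f < 0:
            raise ValueError("viabilities and effects must be >= 0")
        if self.clutch_n < 1:
            raise ValueError(f"clutch_n must be a positive integer, got {self.clutch_n}")
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be a positive integer, got {self.n_reps}")

    @property
    def male_survival(self) -> float:
        return min(1.0, self.v * self.m)

    @property
    def female_survival(self) -> float:
        return min(1.0, self.f)


def expected_male_fraction(v: float, m: float = 1.0, f: float = 1.0) -> float:
    """Closed-form expected F1 male fraction ``s / (s + f')``.

    Equals 1/2 exactly when male and female survivals match (the Mendelian
    expectation under full rescue).
    """
    if v < 0 or m < 0 or f < 0:
        raise ValueError("viabilities and effects must be >= 0")
    s = min(1.0, v * m)
    f_eff = min(1.0, f)
    if s + f_eff == 0:
        raise ValueError("no survivors: both sex-specific survivals are zero")
    return s / (s + f_eff)


def _line_rng(seed: int, counter: int) -> np.random.Generator:
    # counter-split streams: stable per line regardless of simulation order
    return np.random.default_rng([seed, counter])


def _simulate_counts(
    config: SimConfig, n: int, rng: np.random.Generator, m: Optional[float] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised tallies for ``n`` independent crosses."""
    effect = config.m if m is None else m
    s = min(1.0, config.v * effect)
    if config.poisson_clutch:
        clutch = rng.poisson(config.clutch_n, size=n)
    else:
        clutch = np.full(n, config.clutch_n)
    male_zygotes = rng.binomial(clutch, 0.5)
    males = rng.binomial(male_zygotes, s)
    females = rng.binomial(clutch - male_zygotes, config.female_survival)
    return males, females


def simulate_cross(
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    line_id: str = "sim",
) -> CrossTally:
    """Simulate one cross; identical (config, seed) gives an identical tally."""
    if rng is None:
        rng = _line_rng(config.seed, 1)
    males, females = _simulate_counts(config, 1, rng)
    m, f = int(males[0]), int(females[0])
    if m + f == 0:
        raise RuntimeError(f"{line_id}: simulated cross produced no survivors")
    return CrossTally(line_id=line_id, males=m, females=f)


def estimate_effect(tally: CrossTally, v: float) -> float:
    """Method-of-moments modifier effect ``(males/females) / v`` (f = 1).

    Inverts the generative model: at the expected tallies it recovers the
    generating ``m`` whenever ``v * m <= 1``.
    """
    if v <= 0:
        raise ValueError(f"baseline viability must be > 0, got {v}")
    if tally.females < 1:
        raise ValueError(f"{tally.line_id}: zero females, effect not estimable")
    return (tally.males / tally.females) / v


@dataclass(frozen=True)
class PowerResult:
    """Monte-Carlo detection probability with its binomial standard error."""

    power: float
    se: float
    n_reps: int
    target_class: str


def _classified_fractions(
    config: SimConfig, screen_config: ScreenConfig, m: float
) -> Dict[str, float]:
    rng = _line_rng(config.seed, 1)
    males, females = _simulate_counts(config, config.n_reps, rng, m=m)
    total = males + females
    ok = total > 0
    counts = {ENHANCER: 0, SUPPRESSOR: 0, NONMODIFIER: 0}
    for mm, tt in zip(males[ok], total[ok]):
        counts[classify(100.0 * mm / tt, screen_config)] += 1
    n = int(ok.sum())
    return {k: v / n for k, v in counts.items()}


def detection_power(
    m: float,
    config: SimConfig,
    screen_config: ScreenConfig = ScreenConfig(),
) -> PowerResult:
    """Probability that a cross with true effect ``m`` is classified correctly.

    The target class is the one implied by ``m`` (suppressor above 1,
    enhancer below); ``m = 1`` has no true class — use
    :func:`false_positive_rate` instead.
    """
    if config.n_reps < 100:
        raise ValueError("detection power needs n_reps >= 100")
    if m == 1:
        raise ValueError("m = 1 has no true class; use false_positive_rate")
    target = SUPPRESSOR if m > 1 else ENHANCER
    fractions = _classified_fractions(config, screen_config, m)
    power = fractions[target]
    se = math.sqrt(power * (1.0 - power) / config.n_reps)
    return PowerResult(power=power, se=se, n_reps=config.n_reps, target_class=target)


def false_positive_rate(
    config: SimConfig,
    screen_config: ScreenConfig = ScreenConfig(),
) -> PowerResult:
    """Fraction of unmodified (m = 1) crosses misclassified as modifiers."""
    if config.n_reps < 100:
        raise ValueError("false positive rate needs n_reps >= 100")
    fractions = _classified_fractions(config, screen_config, 1.0)
    rate = fractions[ENHANCER] + fractions[SUPPRESSOR]
    se = math.sqrt(rate * (1.0 - rate) / config.n_reps)
    return PowerResult(power=rate, se=se, n_reps=config.n_reps, target_class="any")


EffectSpec = Union[float, Dict[float, float], Sequence[Tuple[float, float]]]


def _normalise_effect_spec(effect_spec: EffectSpec) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(effect_spec, (int, float)):
        return np.array([float(effect_spec)]), np.array([1.0])
    if isinstance(effect_spec, dict):
        items = list(effect_spec.items())
    else:
        items = list(effect_spec)
    if not items:
        raise ValueError("effect_spec is empty")
    effects = np.array([float(m) for m, _ in items])
    weights = np.array([float(w) for _, w in items])
    if np.any(effects < 0) or np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError(f"invalid effect distribution {effect_spec!r}")
    return effects, weights / weights.sum()


@dataclass(frozen=True)
class SimScreen:
    """A synthetic screen table: per-line true effects and simulated tallies."""

    lines: Tuple[Tuple[str, float, CrossTally], ...]
    config: SimConfig

    def tallies(self) -> List[CrossTally]:
        return [t for _, _, t in self.lines]

    def to_tsv(self) -> str:
        """Screen-TSV dialect plus a ``true_m`` column; byte-deterministic."""
        rows = ["line_id\tbreakpoints\tmales\tfemales\ttrue_m"]
        for line_id, true_m, tally in self.lines:
            rows.append(f"{line_id}\t\t{tally.males}\t{tally.females}\t{true_m:g}")
        return "\n".join(rows) + "\n"


def generate_screen_table(
    n_lines: int,
    effect_spec: EffectSpec,
    config: SimConfig,
) -> SimScreen:
    """Simulate a whole screen with per-line effects drawn from a mixture.

    ``effect_spec`` is a point mass (scalar) or a mapping/list of
    ``effect -> weight``.  Line ``i`` draws from stream ``(seed, i+1)``;
    the effect assignment uses stream ``(seed, 0)``.
    """
    if n_lines < 1:
        raise ValueError(f"n_lines must be >= 1, got {n_lines}")
    effects, probs = _normalise_effect_spec(effect_spec)
    assign_rng = _line_rng(config.seed, 0)
    true_ms = assign_rng.choice(effects, size=n_lines, p=probs)
    lines = []
    for i, true_m in enumerate(true_ms):
        line_cfg = replace(config, m=float(true_m))
        rng = _line_rng(config.seed, i + 1)
        tally = simulate_cross(line_cfg, rng=rng, line_id=f"sim{i + 1:04d}")
        lines.append((tally.line_id, float(true_m), tally))
    return SimScreen(lines=tuple(lines), config=config)
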