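"""Scoring of the one-generation (F1) dominant-modifier screen.

Each tested line contributes a single cross tally: the number of surviving F1
males (which express the PAX7-FOXO1 transgene) and control females (rescued
by the X-linked Gal80).  The screen statistic is the percentage of males in
the F1 adults; against the 22% semilethal baseline the fold change
``pct / 22`` classifies a line as an enhancer (fold <= 0.5), a suppressor
(fold >= 1.9) or a nonmodifier.

Thresholds are applied to the *display-rounded* fold, matching how the
published tables were scored: percentages round half-up to integers, folds to
one decimal place when that rounding reaches 1.0 and to two decimal places
otherwise.  So in raw terms a suppressor is fold >= 1.85 and an enhancer is
fold <= 0.505.

An alternative ``"sd"`` threshold mode classifies lines falling one sample
standard deviation above/below the screen mean, the rule the fold cutoffs
were originally derived from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import List, Optional, Sequence, Tuple

from scipy import stats

__all__ = [
    "CrossTally",
    "ScreenConfig",
    "ScreenRecord",
    "ScreenSummary",
    "ENHANCER",
    "SUPPRESSOR",
    "NONMODIFIER",
    "pct_males",
    "fold_change",
    "display_pct",
    "display_fold",
    "classify",
    "replicate_t_test",
    "score_screen",
    "summarize_screen",
]

ENHANCER = "enhancer"
SUPPRESSOR = "suppressor"
NONMODIFIER = "nonmodifier"

#: tolerance when comparing display-rounded folds against the cutoffs
_EPS = 1e-9


@dataclass(frozen=True)
class CrossTally:
    """Pooled F1 counts for one tested line.

    ``replicates`` optionally carries per-cross (males, females) pairs; their
    sums must equal the pooled counts.  ``is_control`` marks baseline
    (no-deficiency) outcrosses, which are excluded from screen summaries.
    """

    line_id: str
    males: int
    females: int
    breakpoints: Optional[str] = None
    replicates: Optional[Tuple[Tuple[int, int], ...]] = None
    is_control: bool = False

    def __post_init__(self) -> None:
        for label, n in (("males", self.males), ("females", self.females)):
            if not isinstance(n, (int,)) or isinstance(n, bool):
                raise ValueError(f"{self.line_id}: {label} must be an integer, got {n!r}")
            if n < 0:
                raise ValueError(f"{self.line_id}: negative {label} count {n}")
        if self.males + self.females < 1:
            raise ValueError(f"{self.line_id}: empty cross (no scored adults)")
        if self.replicates is not None:
            rm = sum(m for m, _ in self.replicates)
            rf = sum(f for _, f in self.replicates)
            if (rm, rf) != (self.males, self.females):
                raise ValueError(
                    f"{self.line_id}: replicate sums ({rm}, {rf}) do not match "
                    f"pooled counts ({self.males}, {self.females})"
                )

    @property
    def total(self) -> int:
        return self.males + self.females


@dataclass(frozen=True)
class ScreenConfig:
    """Scoring parameters.

    ``baseline_pct`` is the established percentage of F1 males in unmodified
    outcrosses.  ``sd_mean``/``sd_sd`` optionally pin the screen mean and SD
    used in ``"sd"`` threshold mode; left unset they are recomputed from the
    scored lines.
    """

    baseline_pct: float = 22.0
    enhancer_fold_max: float = 0.50
    suppressor_fold_min: float = 1.9
    alpha: float = 0.05
    threshold_mode: str = "fold"
    sd_mean: Optional[float] = None
    sd_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 < self.baseline_pct < 100:
            raise ValueError(f"baseline_pct must be in (0, 100), got {self.baseline_pct}")
        if not self.enhancer_fold_max < 1 < self.suppressor_fold_min:
            raise ValueError(
                "thresholds must bracket 1: "
                f"enhancer_fold_max={self.enhancer_fold_max}, "
                f"suppressor_fold_min={self.suppressor_fold_min}"
            )
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.threshold_mode not in ("fold", "sd"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")


@dataclass(frozen=True)
class ScreenRecord:
    """One scored line: statistic, fold change, class and significance."""

    tally: CrossTally
    pct_males: float
    fold_change: float
    classification: str
    p_value: Optional[float] = None
    significant: Optional[bool] = None

    @property
    def line_id(self) -> str:
        return self.tally.line_id


@dataclass(frozen=True)
class ScreenSummary:
    n_lines: int
    mean_pct: float
    sd_pct: float
    n_suppressors: int
    n_enhancers: int
    baseline_pct: float


def _round_half_up(x: float, ndigits: int) -> float:
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


def pct_males(tally: CrossTally) -> float:
    """Unrounded percentage of F1 males among all scored F1 adults."""
    if tally.total < 1:
        raise ValueError(f"{tally.line_id}: empty cross")
    return 100.0 * tally.males / tally.total


def display_pct(pct: float) -> str:
    """Integer display form (half-up), e.g. 21.85 -> ``"22%"``."""
    return f"{_round_half_up(pct, 0):.0f}%"


def fold_change(pct: float, config: ScreenConfig = ScreenConfig()) -> float:
    """Unrounded ratio of the observed percentage to the baseline."""
    return pct / config.baseline_pct


def _display_fold_value(fold: float) -> float:
    r1 = _round_half_up(fold, 1)
    return r1 if r1 >= 1.0 else _round_half_up(fold, 2)


def display_fold(fold: float) -> str:
    """Published display form: one decimal at/above 1.0, two below."""
    value = _display_fold_value(fold)
    return f"{value:.1f}" if value >= 1.0 else f"{value:.2f}"


def classify(
    pct: float,
    config: ScreenConfig = ScreenConfig(),
    mean_pct: Optional[float] = None,
    sd_pct: Optional[float] = None,
) -> str:
    """Classify one line's percentage under the configured thresholds.

    In ``"fold"`` mode the display-rounded fold change is compared with the
    cutoffs; in ``"sd"`` mode the raw percentage is compared with
    mean +/- 1 SD (supplied via arguments or pinned in the config).
    """
    if config.threshold_mode == "sd":
        mean = config.sd_mean if mean_pct is None else mean_pct
        sd = config.sd_sd if sd_pct is None else sd_pct
        if mean is None or sd is None:
            raise ValueError("sd threshold mode requires the screen mean and SD")
        if pct >= mean + sd:
            return SUPPRESSOR
        if pct <= mean - sd:
            return ENHANCER
        return NONMODIFIER
    fold = _display_fold_value(fold_change(pct, config))
    if fold <= config.enhancer_fold_max + _EPS:
        return ENHANCER
    if fold >= config.suppressor_fold_min - _EPS:
        return SUPPRESSOR
    return NONMODIFIER


def replicate_t_test(
    line_pcts: Sequence[float], control_pcts: Sequence[float]
) -> float:
    """Two-tailed p-value of the equal-variance two-sample t-test.

    Operates on per-cross male percentages of a tested line versus parallel
    control crosses, the per-modifier significance test of the screen.
    """
    if len(line_pcts) < 2 or len(control_pcts) < 2:
        raise ValueError("replicates required: each group needs >= 2 crosses")
    if (
        len(set(line_pcts)) == 1
        and len(set(control_pcts)) == 1
        and line_pcts[0] == control_pcts[0]
    ):
        return 1.0  # zero t statistic, degenerate zero variance
    result = stats.ttest_ind(list(line_pcts), list(control_pcts), equal_var=True)
    return float(result.pvalue)


def score_screen(
    tallies: Sequence[CrossTally],
    config: ScreenConfig = ScreenConfig(),
    control_replicate_pcts: Optional[Sequence[float]] = None,
) -> List[ScreenRecord]:
    """Score every line: percentage, fold, class, significance when possible.

    Classification is never gated on significance; when a line carries
    replicate tallies and ``control_replicate_pcts`` is given, the t-test
    p-value is reported alongside.  In ``"sd"`` mode the thresholds come from
    the deficiency lines themselves unless pinned in the config.
    """
    if not tallies:
        raise ValueError("no records: screen input is empty")
    pcts = [pct_males(t) for t in tallies]
    mean = sd = None
    if config.threshold_mode == "sd" and (config.sd_mean is None or config.sd_sd is None):
        screen_pcts = [p for t, p in zip(tallies, pcts) if not t.is_control]
        if len(screen_pcts) < 2:
            raise ValueError("sd threshold mode needs >= 2 deficiency lines")
        mean = sum(screen_pcts) / len(screen_pcts)
        sd = math.sqrt(
            sum((p - mean) ** 2 for p in screen_pcts) / (len(screen_pcts) - 1)
        )
    records = []
    for tally, pct in zip(tallies, pcts):
        p_value = None
        if tally.replicates is not None and control_replicate_pcts is not None:
            rep_pcts = [100.0 * m / (m + f) for m, f in tally.replicates if m + f > 0]
            if len(rep_pcts) >= 2:
                p_value = replicate_t_test(rep_pcts, control_replicate_pcts)
        records.append(
            ScreenRecord(
                tally=tally,
                pct_males=pct,
                fold_change=fold_change(pct, config),
                classification=classify(pct, config, mean, sd),
                p_value=p_value,
                significant=None if p_value is None else bool(p_value < config.alpha),
            )
        )
    return records


def summarize_screen(
    records: Sequence[ScreenRecord], config: ScreenConfig = ScreenConfig()
) -> ScreenSummary:
    """Screen-wide mean, sample SD and class counts over deficiency lines.

    Control outcrosses are excluded.  The SD uses the n-1 denominator.
    """
    screen = [r for r in records if not r.tally.is_control]
    if len(screen) < 2:
        raise ValueError("summary needs >= 2 deficiency records")
    pcts = [r.pct_males for r in screen]
    mean = sum(pcts) / len(pcts)
    sd = math.sqrt(sum((p - mean) ** 2 for p in pcts) / (len(pcts) - 1))
    return ScreenSummary(
        n_lines=len(screen),
        mean_pct=mean,
        sd_pct=sd,
        n_suppressors=sum(r.classification == SUPPRESSOR for r in screen),
        n_enhancers=sum(r.classification == ENHANCER for r in screen),
        baseline_pct=config.baseline_pct,
    )
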