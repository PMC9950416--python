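"""Ethogram representation and the study's group statistics.

Responses to the first unexpected collapse of a manipulated step are
annotated as time intervals of three categories — compensation
(rapid adaptive postural correction), investigation (targeted
interaction with the obstacle) and halting (cessation of the ongoing
motor program with maintained posture) — aligned so that first contact
with the manipulated step is time zero.  Binary per-animal outcomes
(first response halting, dominant response halting, halting fraction
above one third) are cross-tabulated against the group and tested with
the chi-square test for contingency with Yates continuity correction.
Crossing-time and posture comparisons use Student's unpaired t-test,
available both from raw samples and from printed summary statistics
(mean, SD, n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

CATEGORIES = ("compensation", "investigation", "halting")


# ---------------------------------------------------------------------------
# types

@dataclass(frozen=True)
class EthogramInterval:
    category: str
    onset: float                  # s after first contact
    offset: float
    source: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not self.onset < self.offset:
            raise ValueError("interval onset must precede offset")
        if self.onset < 0:
            raise ValueError("intervals start at or after first contact")


@dataclass(frozen=True)
class Ethogram:
    animal_id: str
    group: str                    # "control" | "lesion" | "extended"
    intervals: tuple[EthogramInterval, ...]
    crossed_at: float | None = None
    ear_flicks: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.intervals, key=lambda i: i.onset))
        for a, b in zip(ordered, ordered[1:]):
            if b.onset < a.offset:
                raise ValueError(
                    f"overlapping intervals for {self.animal_id}: "
                    f"{a.category} [{a.onset}, {a.offset}) and {b.category} "
                    f"[{b.onset}, {b.offset}); truncate the earlier "
                    "interval's offset to the later onset to repair")
        if self.crossed_at is not None and ordered \
                and ordered[-1].offset > self.crossed_at:
            raise ValueError("intervals must precede the crossing time")
        object.__setattr__(self, "intervals", ordered)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p: float


# ---------------------------------------------------------------------------
# outcomes

def first_response(ethogram: Ethogram) -> str:
    """Category of the earliest-onset interval."""
    if not ethogram.intervals:
        raise ValueError(f"empty ethogram for {ethogram.animal_id}")
    return ethogram.intervals[0].category


def _durations_in_window(ethogram: Ethogram,
                         window_s: float) -> dict[str, float]:
    if window_s <= 0:
        raise ValueError("window must be positive")
    totals = {c: 0.0 for c in CATEGORIES}
    for iv in ethogram.intervals:
        lo = max(iv.onset, 0.0)
        hi = min(iv.offset, window_s)
        if hi > lo:
            totals[iv.category] += hi - lo
    return totals


def dominant_response(ethogram: Ethogram, window_s: float = 5.0) -> str:
    """Category with maximal total duration inside [0, window]; ties are
    broken by earliest onset.  Intervals are clipped at the window edge."""
    totals = _durations_in_window(ethogram, window_s)
    if all(v == 0.0 for v in totals.values()):
        raise ValueError("no interval intersects the window")
    best = max(totals.values())
    tied = {c for c, v in totals.items() if v == best}
    if len(tied) == 1:
        return tied.pop()
    for iv in ethogram.intervals:  # already onset-ordered
        if iv.category in tied and iv.onset < window_s:
            return iv.category
    raise AssertionError("unreachable")  # pragma: no cover


def halting_fraction(ethogram: Ethogram, window_s: float = 5.0) -> float:
    """Halting duration / total annotated duration within the window."""
    totals = _durations_in_window(ethogram, window_s)
    denom = sum(totals.values())
    if denom == 0.0:
        raise ValueError("no annotated time inside the window")
    return totals["halting"] / denom


def exceeds_one_third(fraction: float) -> bool:
    """Strictly more than one third of the response."""
    return fraction > 1.0 / 3.0


# ---------------------------------------------------------------------------
# contingency statistics

def contingency(groups: list[str], outcomes: list[bool]) -> np.ndarray:
    """2x2 cross-tabulation: rows = the two groups (first-appearance
    order), columns = (outcome True, outcome False)."""
    if len(groups) != len(outcomes):
        raise ValueError("groups and outcomes differ in length")
    order: list[str] = []
    for g in groups:
        if g not in order:
            order.append(g)
    if len(order) != 2:
        raise ValueError(f"need exactly two groups, got {order}")
    if not all(isinstance(o, (bool, np.bool_)) for o in outcomes):
        raise ValueError("outcomes must be binary")
    table = np.zeros((2, 2), dtype=np.int64)
    for g, o in zip(groups, outcomes):
        table[order.index(g), 0 if o else 1] += 1
    return table


def chi_square_yates(table: np.ndarray) -> TestResult:
    """Chi-square test for a 2x2 contingency table with Yates continuity
    correction.

    statistic = N * max(|ad - bc| - N/2, 0)^2 / (r1 r2 c1 c2), df = 1;
    the continuity correction floors at zero so identical rows yield a
    statistic of exactly 0 and p = 1.
    """
    t = np.asarray(table, dtype=np.float64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    (a, b), (c, d) = t
    n = t.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("table has a zero margin")
    corrected = max(abs(a * d - b * c) - n / 2.0, 0.0)
    statistic = n * corrected ** 2 / (r1 * r2 * c1 * c2)
    p = float(_stats.chi2.sf(statistic, df=1))
    return TestResult(float(statistic), 1, p)


def chi_square(table: np.ndarray) -> TestResult:
    """Uncorrected Pearson chi-square on a 2x2 table (for comparison
    with the Yates-corrected statistic)."""
    t = np.asarray(table, dtype=np.float64)
    (a, b), (c, d) = t
    n = t.sum()
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("table has a zero margin")
    statistic = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return TestResult(float(statistic), 1, float(_stats.chi2.sf(statistic, 1)))


# ---------------------------------------------------------------------------
# t-tests

def t_test(mean1: float, sd1: float, n1: int,
           mean2: float, sd2: float, n2: int) -> TestResult:
    """Student's unpaired two-sample t-test from summary statistics.

    Pooled-variance form: df = n1 + n2 - 2, two-sided p.  This is the
    form needed to reproduce printed mean +/- SD tables.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    delta = mean1 - mean2
    if se == 0.0:
        if delta == 0.0:
            return TestResult(0.0, df, 1.0)
        warnings.warn("zero pooled variance with nonzero mean difference",
                      stacklevel=2)
        return TestResult(np.inf, df, 0.0)
    t = delta / se
    p = 2.0 * float(_stats.t.sf(abs(t), df))
    return TestResult(float(t), df, p)


def t_test_raw(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Raw-sample overload; reduces exactly to the summary form."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    return t_test(float(x.mean()), float(x.std(ddof=1)), len(x),
                  float(y.mean()), float(y.std(ddof=1)), len(y))
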