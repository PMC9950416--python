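"""Crossing-level and group-level behavioral measures.

Includes crossing times and the skilled-performance criterion (mean
crossing time under 8 s, i.e. less than 1 s per obstacle), transition-
session splits (the 20 trials immediately preceding a mid-session state
change vs the remainder), slips per crossing by limb, nose posture at
the first manipulated step (by condition and by trial history), spatial
speed profiles with approach-speed baselining, the per-animal speedup
index, and jump-probability statistics with jumper classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rungwalk.ethogram import TestResult, t_test_raw
from rungwalk.events import Crossing, SlipEvent, StepEvent
from rungwalk.geometry import CourseGeometry
from rungwalk.tracking import PoseSample


# ---------------------------------------------------------------------------
# types

@dataclass(frozen=True)
class TrialRecord:
    crossing: Crossing
    session_day: int
    trial_ordinal: int            # 1-based within session
    state: str                    # "stable" | "unstable"
    crossing_time: float          # s
    prev_states: tuple[str, str] | None = None
    step_events: tuple[StepEvent, ...] = ()
    slip_events: tuple[SlipEvent, ...] = ()
    animal_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if self.crossing_time <= 0:
            raise ValueError("crossing_time must be positive")


@dataclass(frozen=True)
class PostureSample:
    progression: float            # cm, + = forward of the reference
    height: float                 # cm, + = up
    trigger_step: int
    trial: TrialRecord | None = None


@dataclass(frozen=True)
class SpeedProfile:
    segment_speeds: np.ndarray    # cm/s, NaN where unmeasurable
    baseline: float               # mean approach speed, cm/s
    baselined: np.ndarray         # speeds - baseline
    n_approach: int


@dataclass(frozen=True)
class JumpStats:
    animal_id: str | None
    probability: float
    n_crossings: int
    weight_g: float | None = None
    jumper: bool = False


# ---------------------------------------------------------------------------
# crossing times

def crossing_time(crossing: Crossing, frame_rate: float) -> float:
    """Duration of the crossing in seconds."""
    if crossing.end <= crossing.start:
        raise ValueError("zero-length crossing")
    return (crossing.end - crossing.start) / frame_rate


def meets_performance_criterion(mean_time_s: float,
                                limit_s: float = 8.0) -> bool:
    """Skilled-performance criterion: mean crossing time strictly under
    ``limit_s`` (less than 1 s per obstacle over eight obstacles)."""
    return mean_time_s < limit_s


def session_summary(records: list[TrialRecord]) -> pd.DataFrame:
    """Mean +/- SD crossing times grouped by (group, session_day)."""
    df = pd.DataFrame({
        "group": [r.group for r in records],
        "session_day": [r.session_day for r in records],
        "crossing_time": [r.crossing_time for r in records],
    })
    out = (df.groupby(["group", "session_day"])["crossing_time"]
             .agg(mean="mean", sd="std", n="count").reset_index())
    out["meets_criterion"] = out["mean"].map(meets_performance_criterion)
    return out


def split_transition_session(records: list[TrialRecord], change_trial: int,
                             n_pre: int = 20,
                             ) -> tuple[list[TrialRecord], list[TrialRecord]]:
    """Split a transition session at the state change.

    ``change_trial`` is the 1-based ordinal of the first post-change
    trial.  Returns (pre, post) where pre holds the ``n_pre`` trials
    immediately preceding the change (all available, with a warning,
    when fewer exist).
    """
    ordered = sorted(records, key=lambda r: r.trial_ordinal)
    pre = [r for r in ordered if r.trial_ordinal < change_trial]
    post = [r for r in ordered if r.trial_ordinal >= change_trial]
    if len(pre) < n_pre:
        warnings.warn(
            f"only {len(pre)} pre-change trials available (wanted {n_pre})",
            stacklevel=2)
    else:
        pre = pre[-n_pre:]
    return pre, post


# ---------------------------------------------------------------------------
# slips

def slips_per_crossing(slips: list[SlipEvent], n_crossings: int,
                       limb: str | None = None) -> float:
    """Confirmed slips per crossing, optionally restricted to one limb."""
    if n_crossings <= 0:
        raise ValueError("need at least one crossing")
    count = sum(1 for s in slips if s.confirmed
                and (limb is None or s.limb == limb))
    return count / n_crossings


# ---------------------------------------------------------------------------
# posture

def posture_at_step(poses: list[PoseSample], event: StepEvent,
                    geometry: CourseGeometry, direction_sign: int,
                    reference_cm: tuple[float, float] | None = None,
                    ) -> PostureSample | None:
    """Nose posture at the moment of a step event.

    progression = (nose x - reference x) in the travel direction, cm;
    height = nose height - reference height, cm (upward positive).  The
    default reference is the near edge of the event's step at reference
    height 0 (the step-top surface); analyses typically re-reference
    heights to a per-animal mean via :func:`mean_nose_height`.

    Returns None (sample skipped) when the pose at the event frame is
    missing or invalid.
    """
    pose = next((p for p in poses if p.frame_index == event.frame), None)
    if pose is None or not pose.valid:
        return None
    x_cm, y_cm = geometry.px_to_cm(*pose.nose)
    if reference_cm is None:
        reference_cm = (geometry.near_edge(event.step_index, direction_sign),
                        0.0)
    progression = (x_cm - reference_cm[0]) * direction_sign
    height = y_cm - reference_cm[1]
    return PostureSample(progression, height, event.step_index)


def mean_nose_height(samples: list[PostureSample]) -> float:
    """Per-animal mean nose height over analyzed trials — the height
    reference used when comparing sessions."""
    return float(np.mean([s.height for s in samples]))


def condition_posture_stats(samples: list[PostureSample],
                            conditioning: str = "current_state",
                            ) -> pd.DataFrame:
    """Per-condition posture statistics and between-condition t-tests.

    ``conditioning`` is "current_state" (trial state) or
    "prev_two_states" (both previous trials stable vs both unstable;
    mixed histories are excluded).  Returns a tidy frame with one row
    per (condition, measure) and columns mean/sd/n plus the two-sample
    t-test p-value when both conditions have at least two samples.
    """
    rows = []
    for s in samples:
        trial = s.trial
        if trial is None:
            continue
        if conditioning == "current_state":
            cond = trial.state
        elif conditioning == "prev_two_states":
            if trial.prev_states is None or \
                    trial.prev_states[0] != trial.prev_states[1]:
                continue
            cond = trial.prev_states[0]
        else:
            raise ValueError(f"unknown conditioning {conditioning!r}")
        rows.append((cond, s.progression, s.height))
    df = pd.DataFrame(rows, columns=["condition", "progression", "height"])
    records = []
    for measure in ("progression", "height"):
        groups = {c: g[measure].to_numpy()
                  for c, g in df.groupby("condition")}
        test: TestResult | None = None
        if len(groups) == 2 and all(len(v) >= 2 for v in groups.values()):
            a, b = (groups[c] for c in sorted(groups))
            test = t_test_raw(a, b)
        for cond, vals in sorted(groups.items()):
            records.append({
                "measure": measure, "condition": cond,
                "mean": float(np.mean(vals)), "sd": float(np.std(vals, ddof=1))
                if len(vals) > 1 else np.nan,
                "n": len(vals),
                "p": test.p if test is not None else np.nan,
            })
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# speed profiles

def default_segments(geometry: CourseGeometry) -> np.ndarray:
    """Segment boundaries (cm): one segment per step-plus-gap interval,
    with the end margins folded into the first and last segments."""
    pitch = geometry.step_width + geometry.gap_width
    inner = [geometry.margin + k * pitch for k in range(1, geometry.n_steps)]
    return np.array([0.0, *inner, geometry.course_length])


def approach_segment_count(geometry: CourseGeometry,
                           direction_sign: int,
                           segments: np.ndarray) -> int:
    """Number of segments strictly before the first manipulated step in
    the travel direction."""
    first = geometry.first_center_step(direction_sign)
    edge = geometry.near_edge(first, direction_sign)
    if direction_sign > 0:
        # segments whose upper bound does not pass the edge
        return int(np.searchsorted(segments, edge, side="right") - 1)
    # R->L: segments whose lower bound lies at or beyond the edge
    return int(np.sum(segments[:-1] >= edge))


def speed_profile(times: np.ndarray, xs_cm: np.ndarray,
                  geometry: CourseGeometry, direction_sign: int,
                  segments: np.ndarray | None = None) -> SpeedProfile:
    """Per-segment speeds with approach-speed baselining.

    Each spatial segment's speed is its length divided by the time the
    nose took to traverse it (NaN when not fully traversed).  The
    baseline is the mean speed over the approach segments — those
    before the first manipulated step in the travel direction — and is
    subtracted from every segment's speed.
    """
    if segments is None:
        segments = default_segments(geometry)
    n_seg = len(segments) - 1
    speeds = np.full(n_seg, np.nan)
    # traversal order follows the direction of travel
    x = xs_cm if direction_sign > 0 else geometry.course_length - xs_cm
    bounds = segments if direction_sign > 0 else \
        (geometry.course_length - segments)[::-1]
    order = np.arange(n_seg) if direction_sign > 0 else \
        np.arange(n_seg)[::-1]
    for pos, seg in enumerate(order):
        lo, hi = bounds[pos], bounds[pos + 1]
        t_in = _first_passage(times, x, lo)
        t_out = _first_passage(times, x, hi)
        if t_in is not None and t_out is not None and t_out > t_in:
            speeds[seg] = (hi - lo) / (t_out - t_in)
    n_app = approach_segment_count(geometry, direction_sign, segments)
    if direction_sign > 0:
        approach = speeds[:n_app]
    else:
        approach = speeds[n_seg - n_app:]
    approach = approach[np.isfinite(approach)]
    if approach.size == 0:
        raise ValueError("no valid approach segments to set the baseline")
    baseline = float(np.mean(approach))
    return SpeedProfile(speeds, baseline, speeds - baseline, n_app)


def _first_passage(times: np.ndarray, x: np.ndarray,
                   target: float) -> float | None:
    """Interpolated time of first passage of x (monotone-ish) past target.

    None when the passage was not observed (already past at the first
    sample, or never reached) — such segments stay unmeasured."""
    above = x >= target
    if above[0]:
        return None
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return None
    i = int(idx[0])
    x0, x1 = x[i - 1], x[i]
    if x1 == x0:
        return float(times[i])
    return float(times[i - 1]
                 + (times[i] - times[i - 1]) * (target - x0) / (x1 - x0))


def speedup_index(stable_profiles: list[SpeedProfile],
                  unstable_profiles: list[SpeedProfile]) -> float:
    """Sum over segments of (mean stable - mean unstable) baselined
    speed; positive values indicate slower crossing of unstable trials.
    Segments missing from either condition are excluded pairwise."""
    if not stable_profiles or not unstable_profiles:
        raise ValueError("need at least one profile per condition")
    stable = np.vstack([p.baselined for p in stable_profiles])
    unstable = np.vstack([p.baselined for p in unstable_profiles])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ms = np.nanmean(stable, axis=0)
        mu = np.nanmean(unstable, axis=0)
    diff = ms - mu
    return float(np.nansum(diff))


# ---------------------------------------------------------------------------
# jumping

def jump_probability(records: list[TrialRecord], geometry: CourseGeometry,
                     animal_id: str | None = None,
                     weight_g: float | None = None) -> JumpStats:
    """Fraction of crossings with no paw contact on either center step."""
    if not records:
        raise ValueError("no crossings")
    center = set(geometry.center_step_indices)
    skipped = sum(
        1 for r in records
        if not any(e.step_index in center for e in r.step_events))
    return JumpStats(animal_id, skipped / len(records), len(records),
                     weight_g)


def classify_jumpers(stats: list[JumpStats],
                     threshold: float = 0.5) -> list[JumpStats]:
    """Flag animals whose skip probability strictly exceeds the
    threshold; jumpers are excluded from randomized-protocol posture
    analyses."""
    out = [JumpStats(s.animal_id, s.probability, s.n_crossings, s.weight_g,
                     s.probability > threshold) for s in stats]
    if out and all(s.jumper for s in out):
        warnings.warn("all animals classified as jumpers; the randomized "
                      "posture analysis set is empty", stacklevel=2)
    return out
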