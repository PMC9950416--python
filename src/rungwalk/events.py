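"""Crossing extraction, step/slip event detection and paw-side labels.

A crossing is a maximal run of frames with a positively identified nose
whose endpoints lie on opposite sides of the course midline.  Step
events are the first supra-threshold peaks in the first derivative of a
step-surface ROI activation trace within a crossing, validated by the
head-position constraint: at the moment of a genuine forelimb contact
the nose must still be before the next step in the travel direction
(hindlimb or tail activations require the head to be further ahead, so
they are rejected).  Slip candidates apply the same peak detection to
the gap ROIs with the head constraint relaxed — zero false negatives at
the cost of false positives — and are confirmed against an external
annotation table, mirroring the semi-automated workflow.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

from rungwalk.geometry import CourseGeometry
from rungwalk.tracking import ActivationTrace, PoseSample


# ---------------------------------------------------------------------------
# types

@dataclass(frozen=True)
class Crossing:
    start: int
    end: int                      # inclusive frame index
    direction: str                # "LR" | "RL"
    crossing_id: int = 0
    animal_id: str | None = None
    session_day: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("crossing must span at least two frames")

    @property
    def direction_sign(self) -> int:
        return 1 if self.direction == "LR" else -1

    @property
    def n_frames(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class StepEvent:
    frame: int
    step_index: int
    limb: str = "fore"
    side: str = "unknown"
    crossing_id: int = 0


@dataclass(frozen=True)
class SlipCandidate:
    candidate_id: int
    frame: int
    gap_index: int
    crossing_id: int | None = None


@dataclass(frozen=True)
class SlipEvent:
    candidate_id: int
    frame: int
    gap_index: int
    confirmed: bool
    limb: str = "unknown"
    reject_reason: str = "none"   # tail | head | exploration | none

    def __post_init__(self) -> None:
        if self.confirmed and self.reject_reason != "none":
            raise ValueError("confirmed slip cannot carry a reject reason")


# ---------------------------------------------------------------------------
# crossings

def extract_crossings(poses: list[PoseSample], geometry: CourseGeometry,
                      max_gap_s: float = 0.25,
                      min_span_frac: float = 0.0) -> list[Crossing]:
    """Find crossings in a pose sequence.

    Runs of valid poses (tolerating up to ``max_gap_s`` of missing
    frames) whose first and last nose x positions fall on opposite
    sides of the course midline become crossings; all other runs are
    discarded.
    """
    max_gap = max(0, int(round(max_gap_s * geometry.frame_rate)))
    runs: list[tuple[int, int]] = []
    start = None
    last_valid = None
    for p in poses:
        if p.valid:
            if start is None:
                start = p.frame_index
            elif last_valid is not None and \
                    p.frame_index - last_valid > max_gap + 1:
                runs.append((start, last_valid))
                start = p.frame_index
            last_valid = p.frame_index
    if start is not None and last_valid is not None:
        runs.append((start, last_valid))

    by_frame = {p.frame_index: p for p in poses if p.valid}
    mid = geometry.midline_cm
    crossings = []
    for start, end in runs:
        if end <= start:
            continue
        x0 = geometry.px_to_cm(*by_frame[start].nose)[0]
        x1 = geometry.px_to_cm(*by_frame[end].nose)[0]
        if (x0 - mid) * (x1 - mid) >= 0:
            continue
        direction = "LR" if x1 > x0 else "RL"
        crossings.append(Crossing(start, end, direction,
                                  crossing_id=len(crossings)))
    return crossings


# ---------------------------------------------------------------------------
# derivative-peak detection

def default_derivative_threshold(trace: ActivationTrace,
                                 factor: float = 5.0) -> float | None:
    """Default detection threshold: ``factor`` times the median absolute
    first difference of the trace (its baseline fluctuation scale).

    Falls back to a quarter of the largest difference when the trace is
    mostly flat (zero median); returns None for a constant trace.
    """
    d = np.abs(np.diff(trace.values))
    if d.size == 0 or d.max() == 0:
        return None
    mad = float(np.median(d))
    return factor * mad if mad > 0 else 0.25 * float(d.max())


def _derivative_peaks(values: np.ndarray, lo: int, hi: int,
                      threshold: float) -> list[int]:
    """Indices (frame of the rising sample) of local maxima of the first
    difference above threshold, within [lo, hi].  A local maximum is
    strictly greater than both neighbors; plateaus yield their earliest
    frame."""
    d = np.diff(values)
    peaks = []
    i = max(lo, 0)
    n = len(d)
    while i < min(hi, n):
        if d[i] > threshold:
            j = i
            while j + 1 < n and d[j + 1] == d[i]:
                j += 1
            left = d[i - 1] if i > 0 else -np.inf
            right = d[j + 1] if j + 1 < n else -np.inf
            if d[i] > left and d[i] > right:
                peaks.append(i + 1)  # the frame after the rise
            i = j + 1
        else:
            i += 1
    return peaks


def detect_step(trace: ActivationTrace, crossing: Crossing,
                threshold: float | None = None) -> int | None:
    """First supra-threshold derivative peak within the crossing, or None."""
    if threshold is None:
        threshold = default_derivative_threshold(trace)
        if threshold is None:
            return None
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    peaks = _derivative_peaks(trace.values, crossing.start, crossing.end,
                              threshold)
    return peaks[0] if peaks else None


def validate_step(candidate_frame: int, step_index: int,
                  poses: list[PoseSample], geometry: CourseGeometry,
                  crossing: Crossing,
                  use_centroid: bool = False) -> StepEvent | str:
    """Apply the head-position constraint to a step candidate.

    Accepted iff the nose (or, optionally, the body centroid) at the
    candidate frame lies before the near edge of the next step in the
    travel direction.  Returns the StepEvent or a rejection reason.
    """
    pose = next((p for p in poses if p.frame_index == candidate_frame), None)
    if pose is None or not pose.valid:
        return "no_pose"
    if use_centroid:
        point = (pose.ellipse.cx, pose.ellipse.cy)
    else:
        point = pose.nose
    x_cm = geometry.px_to_cm(*point)[0]
    sign = crossing.direction_sign
    next_step = step_index + sign
    if 0 <= next_step < geometry.n_steps:
        boundary = geometry.near_edge(next_step, sign)
        if (x_cm - boundary) * sign >= 0:
            return "head_beyond_next_step"
    return StepEvent(candidate_frame, step_index,
                     crossing_id=crossing.crossing_id)


_STEP_LABEL = re.compile(r"step_(\d+)_surface")
_GAP_LABEL = re.compile(r"gap_(\d+)")


def detect_step_events(traces: list[ActivationTrace],
                       crossings: list[Crossing],
                       poses: list[PoseSample],
                       geometry: CourseGeometry,
                       threshold: float | None = None,
                       steps: set[int] | None = None,
                       ) -> tuple[list[StepEvent], list[tuple[int, int, str]]]:
    """Detect and validate step events on all surface traces per crossing.

    Returns accepted events and a list of rejections
    ``(frame, step_index, reason)``.
    """
    accepted: list[StepEvent] = []
    rejected: list[tuple[int, int, str]] = []
    for crossing in crossings:
        for trace in traces:
            m = _STEP_LABEL.fullmatch(trace.label)
            if not m:
                continue
            k = int(m.group(1))
            if steps is not None and k not in steps:
                continue
            frame = detect_step(trace, crossing, threshold)
            if frame is None:
                continue
            result = validate_step(frame, k, poses, geometry, crossing)
            if isinstance(result, StepEvent):
                accepted.append(result)
            else:
                rejected.append((frame, k, result))
    return accepted, rejected


def detect_slip_candidates(traces: list[ActivationTrace],
                           threshold: float | None = None,
                           crossings: list[Crossing] | None = None,
                           ) -> list[SlipCandidate]:
    """Every supra-threshold derivative peak on a gap ROI becomes a
    candidate; no head-position constraint is applied."""
    candidates: list[SlipCandidate] = []
    windows = ([(c.start, c.end, c.crossing_id) for c in crossings]
               if crossings else None)
    for trace in traces:
        m = _GAP_LABEL.fullmatch(trace.label)
        if not m:
            continue
        g = int(m.group(1))
        thr = threshold
        if thr is None:
            thr = default_derivative_threshold(trace)
            if thr is None:
                continue
        if thr <= 0:
            raise ValueError("threshold must be positive")
        if windows is None:
            spans = [(0, len(trace.values) - 1, None)]
        else:
            spans = windows
        for lo, hi, cid in spans:
            for frame in _derivative_peaks(trace.values, lo, hi, thr):
                candidates.append(
                    SlipCandidate(len(candidates), frame, g, cid))
    return candidates


def apply_slip_labels(candidates: list[SlipCandidate],
                      labels: pd.DataFrame) -> list[SlipEvent]:
    """Join candidates to an annotation table.

    ``labels`` columns: ``candidate_id``, ``verdict`` ("genuine" or a
    reject reason among tail/head/exploration), optional ``limb``.
    Unlabeled candidates remain unconfirmed with reason "none".
    """
    known = {c.candidate_id for c in candidates}
    unknown = sorted(set(labels["candidate_id"]) - known)
    if unknown:
        raise KeyError(f"labels reference unknown candidate ids: {unknown}")
    table = labels.set_index("candidate_id")
    events = []
    for c in candidates:
        if c.candidate_id in table.index:
            row = table.loc[c.candidate_id]
            verdict = str(row["verdict"])
            limb = str(row["limb"]) if "limb" in table.columns \
                and pd.notna(row.get("limb")) else "unknown"
            if verdict == "genuine":
                events.append(SlipEvent(c.candidate_id, c.frame, c.gap_index,
                                        True, limb))
            else:
                events.append(SlipEvent(c.candidate_id, c.frame, c.gap_index,
                                        False, limb, verdict))
        else:
            events.append(SlipEvent(c.candidate_id, c.frame, c.gap_index,
                                    False))
    return events


# ---------------------------------------------------------------------------
# paw-side classification

def classify_paw_side(frames: list[np.ndarray], k: int = 2,
                      seed: int = 0, n_bins: int = 32,
                      ) -> tuple[np.ndarray, bool]:
    """Cluster step frames into paw-side groups via brightness histograms.

    Each frame is encoded as its ``n_bins``-bin brightness histogram
    (density) and the encodings are partitioned with seeded K-means
    (10 restarts, best inertia kept).  Returns cluster labels per frame
    and a degeneracy flag (True when fewer than ``k`` distinct
    encodings exist, e.g. identical frames).

    The mapping from clusters to left/right is supplied separately (see
    :func:`map_clusters_to_sides`), mirroring the manual label-correction
    step of the original workflow.
    """
    if len(frames) < k:
        raise ValueError(f"need at least {k} frames, got {len(frames)}")
    lo = min(float(np.min(f)) for f in frames)
    hi = max(float(np.max(f)) for f in frames)
    if hi <= lo:
        hi = lo + 1.0
    enc = np.stack([
        np.histogram(f, bins=n_bins, range=(lo, hi), density=True)[0]
        for f in frames])
    degenerate = len(np.unique(enc, axis=0)) < k
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    with warnings.catch_warnings():
        if degenerate:  # collapse to fewer clusters is expected and flagged
            warnings.simplefilter("ignore", ConvergenceWarning)
        labels = km.fit_predict(enc)
    return labels, degenerate


def map_clusters_to_sides(labels: np.ndarray,
                          known: dict[int, str]) -> list[str]:
    """Map cluster labels to side names using a few known frames
    (``frame index -> "left"/"right"``); unmapped clusters are
    "unknown".  Conflicting assignments within a cluster raise."""
    mapping: dict[int, str] = {}
    for idx, side in known.items():
        cluster = int(labels[idx])
        if mapping.get(cluster, side) != side:
            raise ValueError(f"conflicting side labels for cluster {cluster}")
        mapping[cluster] = side
    return [mapping.get(int(c), "unknown") for c in labels]
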