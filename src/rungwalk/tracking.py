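"""Pose tracking and ROI activation extraction from side-view video.

The tracked state per frame is the nose point and the best-fit body
ellipse of the largest background-subtracted connected component.  ROI
activation traces record, per frame, the total thresholded
background-subtracted intensity inside rectangular regions defined
around each step surface and each inter-step gap; they drive downstream
step/slip event detection.

Coordinates follow the image frame: origin top-left, x rightward, y
downward, 0-based frame indices.  Conversions to cm negate y so that
heights are reported upward (see :mod:`rungwalk.geometry`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from rungwalk.geometry import CourseGeometry

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# types

@dataclass(frozen=True)
class BackgroundModel:
    image: np.ndarray
    method: str = "median"


@dataclass(frozen=True)
class EllipseParams:
    """Moment-based ellipse: centroid (px), semi-axes (px), orientation.

    ``orientation`` is the angle of the major axis measured from the
    image x axis toward positive y (downward), normalized to [0, pi).
    """

    cx: float
    cy: float
    major: float
    minor: float
    orientation: float
    degenerate: bool = False


@dataclass(frozen=True)
class PoseSample:
    frame_index: int
    nose: tuple[float, float] | None
    ellipse: EllipseParams | None
    valid: bool

    def __post_init__(self) -> None:
        if self.valid and (self.nose is None or self.ellipse is None):
            raise ValueError("valid pose requires nose and ellipse")


@dataclass(frozen=True)
class RoiSpec:
    """Axis-aligned rectangular region, half-open pixel bounds."""

    label: str
    x0: int
    y0: int
    x1: int
    y1: int
    role: str  # "surface" | "gap"

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y1), slice(self.x0, self.x1)


@dataclass(frozen=True)
class ActivationTrace:
    label: str
    values: np.ndarray
    frame_rate: float
    role: str = "surface"


@dataclass(frozen=True)
class TrackParams:
    threshold: float = 30.0        # intensity units on |frame - background|
    min_area: int = 30             # px, smallest accepted component
    activation_threshold: float = 30.0


def default_rois(geometry: CourseGeometry,
                 surface_band_cm: tuple[float, float] = (-0.25, 0.75),
                 gap_band_cm: tuple[float, float] = (-1.4, -0.1),
                 inset_cm: float = 0.3) -> list[RoiSpec]:
    """Standard ROI layout: a thin band over each step surface and a band
    below surface level inside each gap.

    Band limits are heights relative to the step-top surface (cm,
    upward positive); ``inset_cm`` widens step ROIs and narrows gap ROIs
    horizontally so that contacts near an edge land in the right region.
    """
    w, h = geometry.frame_size
    rois: list[RoiSpec] = []

    def band(x_lo: float, x_hi: float, y_band: tuple[float, float],
             label: str, role: str) -> RoiSpec:
        x0, y1 = geometry.cm_to_px(x_lo, y_band[0])
        x1, y0 = geometry.cm_to_px(x_hi, y_band[1])
        return RoiSpec(label,
                       max(0, int(math.floor(x0))),
                       max(0, int(math.floor(y0))),
                       min(w, int(math.ceil(x1))),
                       min(h, int(math.ceil(y1))),
                       role)

    for k in range(geometry.n_steps):
        left, right = geometry.step_edges(k)
        rois.append(band(left - inset_cm, right + inset_cm, surface_band_cm,
                         f"step_{k}_surface", "surface"))
    for g in range(geometry.n_steps - 1):
        left, right = geometry.gap_edges(g)
        rois.append(band(left + inset_cm, right - inset_cm, gap_band_cm,
                         f"gap_{g}", "gap"))
    return rois


# ---------------------------------------------------------------------------
# operations

def estimate_background(frames: np.ndarray | list[np.ndarray]) -> BackgroundModel:
    """Pixel-wise temporal median of the sampled frames.

    Robust to transient animal presence: any pixel occupied by the
    animal in fewer than half of the sampled frames recovers the empty
    arena intensity.
    """
    stack = np.asarray(frames)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] == 0:
        raise ValueError("cannot estimate a background from an empty stream")
    return BackgroundModel(np.median(stack, axis=0))


def segment_animal(frame: np.ndarray, background: BackgroundModel,
                   threshold: float, min_area: int = 30) -> np.ndarray | None:
    """Largest 8-connected component of the thresholded absolute
    difference image, or None if its area is below ``min_area``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if frame.shape != background.image.shape:
        raise ValueError("frame and background dimensions differ")
    diff = np.abs(frame.astype(np.float64) - background.image)
    fg = diff > threshold
    labels = measure.label(fg, connectivity=2)
    if labels.max() == 0:
        return None
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    best = int(np.argmax(areas))
    if areas[best] < min_area:
        return None
    return labels == best


def fit_ellipse(mask: np.ndarray) -> EllipseParams:
    """Best-fit ellipse from second-order image moments of the mask.

    The returned semi-axes are those of the ellipse with the same
    normalized second central moments as the component (a uniform filled
    ellipse with semi-axes a, b has variances a^2/4 and b^2/4 along its
    principal directions).
    """
    ys, xs = np.nonzero(mask)
    if xs.size < 5:
        raise ValueError("component area must be at least 5 px")
    cx, cy = xs.mean(), ys.mean()
    dx, dy = xs - cx, ys - cy
    cov = np.array([[np.mean(dx * dx), np.mean(dx * dy)],
                    [np.mean(dx * dy), np.mean(dy * dy)]])
    evals, evecs = np.linalg.eigh(cov)  # ascending
    minor = 2.0 * math.sqrt(max(evals[0], 0.0))
    major = 2.0 * math.sqrt(max(evals[1], 0.0))
    vx, vy = evecs[:, 1]
    theta = math.atan2(vy, vx) % math.pi
    return EllipseParams(cx, cy, major, minor, theta, degenerate=minor == 0.0)


def extract_nose(mask: np.ndarray, ellipse: EllipseParams,
                 heading: float) -> tuple[float, float]:
    """Mask pixel with maximal signed projection on the major axis,
    oriented by the expected travel direction.

    ``heading`` is the sign of travel along image x (+1 rightward).
    Ties are broken by proximity to the major-axis line.
    """
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise ValueError("empty mask")
    ux, uy = math.cos(ellipse.orientation), math.sin(ellipse.orientation)
    if heading != 0 and ux * heading < 0:
        ux, uy = -ux, -uy
    proj = (xs - ellipse.cx) * ux + (ys - ellipse.cy) * uy
    perp = np.abs(-(xs - ellipse.cx) * uy + (ys - ellipse.cy) * ux)
    best = np.lexsort((perp, -proj))[0]
    return float(xs[best]), float(ys[best])


def compute_activations(frames: np.ndarray, background: BackgroundModel,
                        rois: list[RoiSpec],
                        threshold: float) -> list[ActivationTrace]:
    """Per-frame, per-ROI sum of thresholded absolute difference."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    h, w = background.image.shape
    occupancy = np.zeros((h, w), dtype=np.int32)
    for roi in rois:
        if not (0 <= roi.x0 <= roi.x1 <= w and 0 <= roi.y0 <= roi.y1 <= h):
            raise ValueError(f"ROI {roi.label} outside frame bounds")
        occupancy[roi.slices()] += 1
    if (occupancy > 1).any():
        logger.info("overlapping ROIs detected (%d px shared)",
                    int((occupancy > 1).sum()))

    stack = np.asarray(frames, dtype=np.float64)
    diff = np.abs(stack - background.image)
    diff[diff <= threshold] = 0.0
    traces = []
    for roi in rois:
        ys, xs = roi.slices()
        values = diff[:, ys, xs].sum(axis=(1, 2))
        traces.append(ActivationTrace(roi.label, values, 0.0, roi.role))
    return traces


def track(frames: np.ndarray, background: BackgroundModel,
          rois: list[RoiSpec], params: TrackParams | None = None,
          frame_rate: float = 120.0,
          fallback_heading: float = 1.0,
          ) -> tuple[list[PoseSample], list[ActivationTrace]]:
    """Full tracking pass: segment, fit, nose extraction and ROI traces.

    The heading used to disambiguate the major-axis end is the sign of
    the recent centroid displacement, falling back to
    ``fallback_heading`` until the animal has moved.
    """
    params = params or TrackParams()
    poses: list[PoseSample] = []
    last_cx: float | None = None
    heading = fallback_heading
    for i, frame in enumerate(frames):
        mask = segment_animal(frame, background, params.threshold,
                              params.min_area)
        if mask is None:
            poses.append(PoseSample(i, None, None, False))
            continue
        ellipse = fit_ellipse(mask)
        if last_cx is not None and abs(ellipse.cx - last_cx) > 1e-9:
            heading = math.copysign(1.0, ellipse.cx - last_cx)
        last_cx = ellipse.cx
        nose = extract_nose(mask, ellipse, heading)
        poses.append(PoseSample(i, nose, ellipse, True))
    traces = compute_activations(frames, background, rois,
                                 params.activation_threshold)
    traces = [ActivationTrace(t.label, t.values, frame_rate, t.role)
              for t in traces]
    return poses, traces
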