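"""Frame rendering for tracking fixtures.

Frames are grayscale: a static background (dark arena, slightly brighter
step pillars) plus a bright animal blob — an ellipse body with a
triangular nose protrusion whose apex sits exactly at the ground-truth
nose point — and brief bright paw dots at contact/slip locations so that
ROI activation traces can be measured from the rendered video alone.
Appearance is synthetic by design: tracking relies only on segmentation
geometry, not on photorealism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import draw

from rungwalk.geometry import CourseGeometry
from rungwalk.synth.crossing import CrossingGroundTruth


@dataclass(frozen=True)
class RenderStyle:
    bg_intensity: int = 20
    step_intensity: int = 55
    blob_intensity: int = 210
    paw_intensity: int = 235
    body_semi_major_cm: float = 6.0
    body_semi_minor_cm: float = 2.2
    body_lift_cm: float = 1.0       # body center above nose height
    nose_len_cm: float = 2.0
    nose_half_height_cm: float = 0.6
    paw_radius_cm: float = 0.35
    paw_duration_s: float = 0.08
    contact_height_cm: float = 0.3  # paw dot above surface (on a step)
    slip_depth_cm: float = 0.7      # paw dot below surface (in a gap)


def render_background(geometry: CourseGeometry,
                      style: RenderStyle | None = None) -> np.ndarray:
    style = style or RenderStyle()
    w, h = geometry.frame_size
    bg = np.full((h, w), style.bg_intensity, dtype=np.uint8)
    surface = int(round(geometry.surface_y_px))
    for k in range(geometry.n_steps):
        left, right = geometry.step_edges(k)
        x0 = int(round(geometry.cm_to_px(left, 0)[0]))
        x1 = int(round(geometry.cm_to_px(right, 0)[0]))
        bg[surface:, max(0, x0):min(w, x1)] = style.step_intensity
    return bg


def _draw_animal(frame: np.ndarray, geometry: CourseGeometry,
                 style: RenderStyle, x_cm: float, y_cm: float,
                 heading: int, frame_index: int) -> None:
    h, w = frame.shape
    ppc = geometry.px_per_cm
    nx, ny = geometry.cm_to_px(x_cm, y_cm)
    bx = x_cm - heading * (style.nose_len_cm + 0.8 * style.body_semi_major_cm)
    by = y_cm + style.body_lift_cm
    bcx, bcy = geometry.cm_to_px(bx, by)
    a_px = style.body_semi_major_cm * ppc
    b_px = style.body_semi_minor_cm * ppc
    if not (0 <= nx < w and 0 <= ny < h):
        raise ValueError(f"nose path exits the frame at frame {frame_index}")
    # the body may extend past the frame edge (animal entering/leaving);
    # drawing is clipped to the frame
    rr, cc = draw.ellipse(bcy, bcx, b_px, a_px, shape=frame.shape)
    frame[rr, cc] = style.blob_intensity
    # triangular nose: apex at the nose point, base toward the body
    base_x = x_cm - heading * style.nose_len_cm
    b0 = geometry.cm_to_px(base_x, y_cm - style.nose_half_height_cm)
    b1 = geometry.cm_to_px(base_x, y_cm + style.nose_half_height_cm)
    rr, cc = draw.polygon([ny, b0[1], b1[1]], [nx, b0[0], b1[0]],
                          shape=frame.shape)
    frame[rr, cc] = style.blob_intensity
    frame[int(round(ny)), int(round(nx))] = style.blob_intensity


def render_frames(gt: CrossingGroundTruth | None,
                  geometry: CourseGeometry,
                  style: RenderStyle | None = None,
                  n_frames: int | None = None,
                  draw_paws: bool = True,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Render a crossing into a grayscale frame stack.

    Parameters
    ----------
    gt:
        Ground truth to render, or None for an empty arena.
    n_frames:
        Overrides the frame count (required when ``gt`` is None or has an
        empty path; such frames are pure background).

    Returns
    -------
    (frames, background):
        ``frames`` is (T, H, W) uint8; ``background`` is the static
        (H, W) arena frame.
    """
    style = style or RenderStyle()
    bg = render_background(geometry, style)
    path = gt.nose_path if gt is not None else np.empty((0, 2))
    total = len(path) if n_frames is None else n_frames
    frames = np.repeat(bg[None], total, axis=0)
    if gt is None or len(path) == 0:
        return frames, bg

    heading = gt.direction_sign
    rate = gt.frame_rate
    dot_frames = max(2, int(round(style.paw_duration_s * rate)))
    dots: list[tuple[int, int, float, float]] = []  # (f0, f1, x, y)
    for ev in gt.contact_events:
        x = geometry.step_center(ev.step_index)
        f0 = int(round(ev.time_s * rate))
        dots.append((f0, f0 + dot_frames, x, style.contact_height_cm))
    for sl in gt.slip_events:
        gl, gr = geometry.gap_edges(sl.gap_index)
        f0 = int(round(sl.time_s * rate))
        dots.append((f0, f0 + dot_frames, (gl + gr) / 2, -style.slip_depth_cm))

    for i in range(min(total, len(path))):
        frame = frames[i]
        if draw_paws:
            for f0, f1, x, y in dots:
                if f0 <= i < f1:
                    px, py = geometry.cm_to_px(x, y)
                    rr, cc = draw.disk((py, px),
                                       style.paw_radius_cm * geometry.px_per_cm,
                                       shape=frame.shape)
                    frame[rr, cc] = style.paw_intensity
        _draw_animal(frame, geometry, style, path[i, 0], path[i, 1],
                     heading, i)
    return frames, bg
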