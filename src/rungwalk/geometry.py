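"""Course geometry and coordinate conventions.

The obstacle course is a horizontal row of ``n_steps`` rungs of width
``step_width`` cm separated by ``gap_width`` cm gaps, spanning
``course_length`` cm in total (the defaults describe a 48 cm course of
eight 2 cm steps spaced by 4 cm).  Two adjacent interior steps — the
"center" or manipulated steps — can be locked (stable) or released
(unstable) on a per-trial basis.

Two coordinate frames are used throughout the package:

* **assay frame** (cm): ``x`` runs along the travel axis with 0 at the
  left edge of the course; ``y`` is height above the step-top surface,
  positive upward.
* **image frame** (px): origin top-left, ``x`` rightward, ``y`` downward,
  0-based frame indices.  Conversions use ``px_per_cm`` and negate ``y``
  so that reported heights are upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class CourseGeometry:
    """Static description of the obstacle course and the camera.

    Parameters
    ----------
    n_steps:
        Number of rungs in the course.
    step_width, gap_width, course_length:
        Rung width, inter-rung gap and total course span, in cm.  The
        course is centered, so the margin on each side is
        ``(course_length - n_steps*step_width - (n_steps-1)*gap_width)/2``.
    center_step_indices:
        The two adjacent interior steps whose stability is manipulated.
    px_per_cm:
        Camera calibration factor.
    frame_size:
        (width, height) of a video frame in pixels.
    frame_rate:
        Acquisition rate in Hz.
    surface_frac:
        Vertical position of the step-top surface in the frame, as a
        fraction of frame height from the top.
    """

    n_steps: int = 8
    step_width: float = 2.0
    gap_width: float = 4.0
    course_length: float = 48.0
    center_step_indices: tuple[int, int] = (3, 4)
    px_per_cm: float = 24.0
    frame_size: tuple[int, int] = (1280, 680)
    frame_rate: float = 120.0
    surface_frac: float = 0.72

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ValueError("n_steps must be at least 2")
        for name in ("step_width", "gap_width", "course_length", "px_per_cm",
                     "frame_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        a, b = self.center_step_indices
        if b != a + 1 or a < 1 or b > self.n_steps - 2:
            raise ValueError(
                "center_step_indices must be two adjacent interior steps")
        if self.span > self.course_length:
            raise ValueError("steps and gaps do not fit in course_length")

    # -- layout -----------------------------------------------------------

    @property
    def span(self) -> float:
        """Extent covered by steps and gaps, cm."""
        return (self.n_steps * self.step_width
                + (self.n_steps - 1) * self.gap_width)

    @property
    def margin(self) -> float:
        """Clearance between the course edge and the first/last step, cm."""
        return (self.course_length - self.span) / 2.0

    @property
    def midline_cm(self) -> float:
        return self.course_length / 2.0

    def step_edges(self, k: int) -> tuple[float, float]:
        """(left, right) cm of step ``k``'s surface."""
        if not 0 <= k < self.n_steps:
            raise IndexError(f"step index {k} out of range")
        left = self.margin + k * (self.step_width + self.gap_width)
        return left, left + self.step_width

    def gap_edges(self, i: int) -> tuple[float, float]:
        """(left, right) cm of gap ``i`` (between steps ``i`` and ``i+1``)."""
        if not 0 <= i < self.n_steps - 1:
            raise IndexError(f"gap index {i} out of range")
        return self.step_edges(i)[1], self.step_edges(i + 1)[0]

    def step_center(self, k: int) -> float:
        left, right = self.step_edges(k)
        return (left + right) / 2.0

    def near_edge(self, k: int, direction: int) -> float:
        """Edge of step ``k`` first reached when travelling in ``direction``
        (+1 = left-to-right, -1 = right-to-left)."""
        left, right = self.step_edges(k)
        return left if direction > 0 else right

    def first_center_step(self, direction: int) -> int:
        """Index of the first manipulated step met in ``direction``."""
        a, b = self.center_step_indices
        return a if direction > 0 else b

    # -- coordinate conversions ------------------------------------------

    @property
    def x_origin_px(self) -> float:
        return (self.frame_size[0] - self.course_length * self.px_per_cm) / 2.0

    @property
    def surface_y_px(self) -> float:
        return self.frame_size[1] * self.surface_frac

    def cm_to_px(self, x_cm: float, y_cm: float) -> tuple[float, float]:
        """Assay-frame (cm) to image-frame (px); y is negated."""
        return (self.x_origin_px + x_cm * self.px_per_cm,
                self.surface_y_px - y_cm * self.px_per_cm)

    def px_to_cm(self, x_px: float, y_px: float) -> tuple[float, float]:
        return ((x_px - self.x_origin_px) / self.px_per_cm,
                (self.surface_y_px - y_px) / self.px_per_cm)


def scaled_fixture_geometry(px_per_cm: float = 6.0,
                            frame_rate: float = 60.0) -> CourseGeometry:
    """A reduced-resolution geometry convenient for fast fixtures.

    Same physical course, smaller frames and lower frame rate; the image
    width leaves a small border around the course.
    """
    width = int(round(52.0 * px_per_cm))
    height = int(round(width * 0.5))
    return CourseGeometry(px_per_cm=px_per_cm,
                          frame_size=(width, height),
                          frame_rate=frame_rate)
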