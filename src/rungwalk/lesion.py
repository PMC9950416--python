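"""Lesion volumetry from serial-section traced outlines.

Volumes are Cavalieri estimates: the traced lesion cross-sectional area
of each slice times the slice thickness, summed per hemisphere.  A
lesion is classified "large" when its total volume strictly exceeds a
threshold (15 mm^3 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon


@dataclass(frozen=True)
class SliceOutline:
    """One manually traced outline on a serial section.

    ``polygon`` is an (N, 2) array of planar vertices in mm; ``hole``
    marks outlines whose area subtracts (cavities inside a lesion).
    """

    slice_index: int
    hemisphere: str           # "left" | "right"
    polygon: np.ndarray
    kind: str = "lesion"      # "lesion" | "brain"
    hole: bool = False

    def __post_init__(self) -> None:
        poly = np.asarray(self.polygon, dtype=np.float64)
        if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
            raise ValueError("polygon must be an (N>=3, 2) vertex array")
        object.__setattr__(self, "polygon", poly)


@dataclass(frozen=True)
class LesionStack:
    outlines: tuple[SliceOutline, ...]
    slice_thickness: float = 0.1  # mm

    def __post_init__(self) -> None:
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be positive")
        object.__setattr__(self, "outlines", tuple(self.outlines))


@dataclass(frozen=True)
class VolumeReport:
    left_mm3: float
    right_mm3: float
    size_class: str | None = None

    @property
    def total_mm3(self) -> float:
        return self.left_mm3 + self.right_mm3


def polygon_area(polygon: np.ndarray, validate: bool = True) -> float:
    """Absolute shoelace area of a simple polygon, mm^2.

    Orientation-independent; raises on self-intersecting input when
    ``validate`` is set.
    """
    poly = np.asarray(polygon, dtype=np.float64)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise ValueError("polygon must be an (N>=3, 2) vertex array")
    if validate and not _ShapelyPolygon(poly).is_valid:
        raise ValueError("polygon is self-intersecting or degenerate")
    x, y = poly[:, 0], poly[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
                 / 2.0)


def stack_volume(stack: LesionStack, validate: bool = True) -> VolumeReport:
    """Cavalieri volume per hemisphere: sum of traced lesion areas times
    slice thickness.  Hole outlines subtract."""
    lesions = [o for o in stack.outlines if o.kind == "lesion"]
    if not lesions:
        raise ValueError("stack contains no lesion outlines")
    volumes = {"left": 0.0, "right": 0.0}
    seen: set[tuple[str, int]] = set()
    for o in lesions:
        key = (o.hemisphere, o.slice_index)
        if not o.hole:
            if key in seen:
                raise ValueError(
                    f"duplicate slice index {o.slice_index} in "
                    f"{o.hemisphere} hemisphere")
            seen.add(key)
        area = polygon_area(o.polygon, validate=validate)
        volumes[o.hemisphere] += (-area if o.hole else area) \
            * stack.slice_thickness
    for hemi, v in volumes.items():
        if v < 0:
            raise ValueError(f"negative {hemi} volume: holes exceed outlines")
    return VolumeReport(volumes["left"], volumes["right"])


def classify_size(report: VolumeReport | float,
                  threshold_mm3: float = 15.0) -> str:
    """"large" iff the total lesion volume strictly exceeds the
    threshold, else "small"."""
    total = report.total_mm3 if isinstance(report, VolumeReport) else report
    return "large" if total > threshold_mm3 else "small"


def classified_report(report: VolumeReport,
                      threshold_mm3: float = 15.0) -> VolumeReport:
    return VolumeReport(report.left_mm3, report.right_mm3,
                        classify_size(report, threshold_mm3))
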