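"""Insole footprint geometry.

The footprint outline is a smooth, left/right-symmetric template: a
monotone-cubic (PCHIP) half-width profile along the normalized
posterior→anterior axis, scaled to the length and width of each commercial
insole size pair.  Coordinates follow the convention used throughout the
package: origin at the posterior-medial corner of the insole bounding box,
x = medial→lateral in mm, y = posterior→anterior in mm.  In this frame the
medial border is always at low x, for either foot side.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import PchipInterpolator

INSOLE_SIZES = ("38-39", "40-41", "42-43", "44-45")

#: insole (length, width) in mm per size pair.  The 38-39 total surface is
#: the one documented for this template (15787 mm^2); other sizes scale it
#: by the length x width ratio.
SIZE_DIMS: dict[str, tuple[float, float]] = {
    "38-39": (245.0, 80.0),
    "40-41": (257.0, 83.0),
    "42-43": (269.0, 86.0),
    "44-45": (281.0, 89.0),
}

_BASE_SURFACE_MM2 = 15787.0
_BASE_LW = SIZE_DIMS["38-39"][0] * SIZE_DIMS["38-39"][1]

REGIONS = (
    "hindfoot_medial",
    "hindfoot_lateral",
    "midfoot_medial",
    "midfoot_lateral",
    "forefoot_medial",
    "forefoot_lateral",
    "toes",
)

# normalized posterior->anterior boundaries of the region mask
HINDFOOT_MAX = 0.30
MIDFOOT_MAX = 0.55
FOREFOOT_MAX = 0.80

# half-width profile control points: (normalized y, fraction of half width).
# Heel cap, narrow lateral-arch waist, broad metatarsal head band, toe cap.
_PROFILE_KNOTS = (
    (0.00, 0.15),
    (0.03, 0.62),
    (0.10, 0.92),
    (0.20, 0.95),
    (0.30, 0.85),
    (0.42, 0.70),
    (0.50, 0.72),
    (0.62, 0.88),
    (0.72, 1.00),
    (0.82, 0.98),
    (0.90, 0.80),
    (0.97, 0.45),
    (1.00, 0.10),
)

_profile = PchipInterpolator(
    np.array([k[0] for k in _PROFILE_KNOTS]),
    np.array([k[1] for k in _PROFILE_KNOTS]),
)


def validate_size(insole_size: str) -> str:
    if insole_size not in SIZE_DIMS:
        raise ValueError(
            f"unknown insole size {insole_size!r}; expected one of {INSOLE_SIZES}"
        )
    return insole_size


def size_dims(insole_size: str) -> tuple[float, float]:
    """(length, width) of the insole bounding box in mm."""
    validate_size(insole_size)
    return SIZE_DIMS[insole_size]


def total_surface_mm2(insole_size: str) -> float:
    """Nominal total insole surface, scaled from the 38-39 reference."""
    length, width = size_dims(insole_size)
    return _BASE_SURFACE_MM2 * (length * width) / _BASE_LW


def halfwidth(y: np.ndarray | float, insole_size: str) -> np.ndarray | float:
    """Outline half-width (mm) at posterior->anterior coordinate ``y`` (mm)."""
    length, width = size_dims(insole_size)
    u = np.asarray(y, dtype=float) / length
    hw = 0.5 * width * _profile(np.clip(u, 0.0, 1.0))
    hw = np.where((u < 0.0) | (u > 1.0), 0.0, np.maximum(hw, 0.0))
    return hw if hw.ndim else float(hw)


def point_inside(x: float, y: float, insole_size: str) -> bool:
    length, width = size_dims(insole_size)
    if not 0.0 <= y <= length:
        return False
    return abs(x - 0.5 * width) <= halfwidth(y, insole_size)


def rect_inside(
    cx: float, cy: float, w: float, h: float, insole_size: str, n_samples: int = 9
) -> bool:
    """Whether an axis-aligned ``w x h`` rectangle centered at (cx, cy) lies
    inside the footprint outline.

    The outline is convex in x at fixed y, so containment reduces to a
    half-width check sampled along the rectangle's y extent.
    """
    length, width = size_dims(insole_size)
    y0, y1 = cy - 0.5 * h, cy + 0.5 * h
    if y0 < 0.0 or y1 > length:
        return False
    ys = np.linspace(y0, y1, n_samples)
    hw = np.asarray(halfwidth(ys, insole_size))
    return bool(np.all(abs(cx - 0.5 * width) + 0.5 * w <= hw))


def region_of(x: float, y: float, insole_size: str) -> str:
    """Region label of a point under the active footprint mask.

    Hindfoot / midfoot / forefoot / toes bands at 0.30 / 0.55 / 0.80 of the
    insole length; medial/lateral split at the outline midline.  Toes are a
    single label spanning both sides.
    """
    length, width = size_dims(insole_size)
    u = y / length
    medial = x < 0.5 * width
    if u < HINDFOOT_MAX:
        return "hindfoot_medial" if medial else "hindfoot_lateral"
    if u < MIDFOOT_MAX:
        return "midfoot_medial" if medial else "midfoot_lateral"
    if u < FOREFOOT_MAX:
        return "forefoot_medial" if medial else "forefoot_lateral"
    return "toes"


def rects_overlap_area(
    c1: tuple[float, float], wh1: tuple[float, float],
    c2: tuple[float, float], wh2: tuple[float, float],
) -> float:
    """Intersection area of two axis-aligned rectangles given center + size."""
    dx = min(c1[0] + wh1[0] / 2, c2[0] + wh2[0] / 2) - max(
        c1[0] - wh1[0] / 2, c2[0] - wh2[0] / 2
    )
    dy = min(c1[1] + wh1[1] / 2, c2[1] + wh2[1] / 2) - max(
        c1[1] - wh1[1] / 2, c2[1] - wh2[1] / 2
    )
    if dx <= 0.0 or dy <= 0.0:
        return 0.0
    return dx * dy


def rect_gap(
    c1: tuple[float, float], wh1: tuple[float, float],
    c2: tuple[float, float], wh2: tuple[float, float],
) -> float:
    """Separation between two axis-aligned rectangles (negative if they
    overlap): the larger of the per-axis edge-to-edge distances."""
    gx = abs(c1[0] - c2[0]) - 0.5 * (wh1[0] + wh2[0])
    gy = abs(c1[1] - c2[1]) - 0.5 * (wh1[1] + wh2[1])
    return max(gx, gy)
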