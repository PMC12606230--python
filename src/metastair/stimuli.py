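"""Stimulus geometry for the partial-report display.

Two pieces of the display are parametric rather than hand-tuned: the letter
colours, sampled as equidistant points in the CIELAB ``(a*, b*)`` plane so
that neighbouring letters differ by a fixed perceptual distance, and the
letter positions, equispaced on a circle of fixed visual angle.  Both are
pure geometry; rendering, gamut clipping and Lab->RGB conversion are out of
scope here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LabColor",
    "ArrayLayout",
    "ConstraintViolation",
    "wheel_radius",
    "color_wheel",
    "array_positions",
    "n_colors_for",
    "assign_colors",
    "wheel_to_frame",
    "layout_to_frame",
]

#: Chord length (CIELAB units) between adjacent wheel colours used in the study.
ADJACENT_DISTANCE = 149.2975
#: Fixed lightness (L*) of all stimulus colours.
LIGHTNESS = 70.0
#: Radius of the circular letter array, degrees of visual angle.
ARRAY_RADIUS_DEG = 8.81


class ConstraintViolation(ValueError):
    """Raised when a colour assignment would give two adjacent letters the same colour."""


@dataclass(frozen=True)
class LabColor:
    """A CIELAB colour; ``L`` is lightness, ``a`` green-red, ``b`` blue-yellow."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.L, self.a, self.b)):
            raise ValueError("LabColor components must be finite")


@dataclass(frozen=True)
class ArrayLayout:
    """Equispaced positions on a circle of radius ``radius_deg`` (visual angle)."""

    n_items: int
    radius_deg: float
    rotation_rad: float
    angles: np.ndarray = field(repr=False)
    xy: np.ndarray = field(repr=False)


def wheel_radius(n_colors: int, adjacent_distance: float = ADJACENT_DISTANCE) -> float:
    """Radius of the circle on which ``n_colors`` equidistant points sit.

    For points with adjacent chord length ``d`` the radius is
    ``d / (2 sin(pi/n))``; the points are then also equidistant from the grey
    point (a*=0, b*=0) at that radius.
    """
    if n_colors < 2:
        raise ValueError(f"need at least 2 colors, got {n_colors}")
    if adjacent_distance <= 0:
        raise ValueError(f"adjacent_distance must be positive, got {adjacent_distance}")
    return adjacent_distance / (2.0 * math.sin(math.pi / n_colors))


def color_wheel(
    n_colors: int,
    adjacent_distance: float = ADJACENT_DISTANCE,
    L: float = LIGHTNESS,
    phase: float = 0.0,
) -> list[LabColor]:
    """``n_colors`` equidistant CIELAB colours on a circle around the grey point.

    Parameters
    ----------
    n_colors
        Number of colours (the study uses 4 or 5).
    adjacent_distance
        Chord length between adjacent colours, CIELAB units.
    L
        Fixed lightness of every colour.
    phase
        Angle (radians) of the first colour in the (a*, b*) plane; with
        ``phase=0`` the first colour lies on the positive a* axis.
    """
    r = wheel_radius(n_colors, adjacent_distance)
    angles = phase + 2.0 * math.pi * np.arange(n_colors) / n_colors
    return [LabColor(L, r * math.cos(t), r * math.sin(t)) for t in angles]


def array_positions(
    n_items: int, radius_deg: float = ARRAY_RADIUS_DEG, rotation: float = 0.0
) -> ArrayLayout:
    """Equispaced positions for ``n_items`` letters on the stimulus circle.

    ``rotation`` is the global rotation applied on each trial (the array
    rotates randomly trial to trial so letter positions are not fixed).
    """
    if n_items < 1:
        raise ValueError(f"n_items must be >= 1, got {n_items}")
    angles = rotation + 2.0 * math.pi * np.arange(n_items) / n_items
    xy = radius_deg * np.column_stack([np.cos(angles), np.sin(angles)])
    return ArrayLayout(
        n_items=n_items,
        radius_deg=radius_deg,
        rotation_rad=rotation,
        angles=angles,
        xy=xy,
    )


def n_colors_for(n_items: int) -> int:
    """Wheel size rule: five colours for 5-, 9- or 13-item arrays, else four.

    With a cyclic assignment this guarantees that no two neighbouring letters
    (including the wrap-around pair) share a colour.
    """
    return 5 if n_items in (5, 9, 13) else 4


def assign_colors(layout: ArrayLayout, wheel: list[LabColor]) -> np.ndarray:
    """Cyclic colour indices for the letters of ``layout``.

    Letter ``i`` gets wheel colour ``i mod len(wheel)`` so neighbouring
    letters always receive adjacent wheel colours (fixed perceptual
    difference).  Raises :class:`ConstraintViolation` if the wrap-around pair
    would collide, i.e. the chosen wheel size is wrong for this array size.
    """
    k = len(wheel)
    if k not in (4, 5):
        raise ValueError(f"wheel must have 4 or 5 colors, got {k}")
    n = layout.n_items
    idx = np.arange(n) % k
    if n > 1 and idx[-1] == idx[0]:
        raise ConstraintViolation(
            f"cyclic assignment of {k} colors to {n} items repeats a color "
            "on the wrap-around adjacency"
        )
    return idx


def wheel_to_frame(wheel: list[LabColor]) -> pd.DataFrame:
    """Serialize a colour wheel as a table (index, L, a, b)."""
    return pd.DataFrame(
        {
            "index": np.arange(len(wheel)),
            "L": [c.L for c in wheel],
            "a": [c.a for c in wheel],
            "b": [c.b for c in wheel],
        }
    )


def layout_to_frame(layout: ArrayLayout) -> pd.DataFrame:
    """Serialize an array layout as a table (index, angle_rad, x_deg, y_deg)."""
    return pd.DataFrame(
        {
            "index": np.arange(layout.n_items),
            "angle_rad": layout.angles,
            "x_deg": layout.xy[:, 0],
            "y_deg": layout.xy[:, 1],
        }
    )
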