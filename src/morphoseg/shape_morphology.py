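"""Structuring-element morphology and extent-based shape validation.

A candidate segment is accepted or rejected by comparing its pixel extents —
how far its mask reaches up, down, left and right of an anchor (normally the
center of mass) — against a :class:`ShapeKernel` template. The template is
the morphological shape definition: e.g. a forehead patch reaching 43 px up,
60 px down, 7 px left and 15 px right of its centroid. Extents are measured
to the mask's bounding box; an alternative per-ray mode follows contiguous
runs from the anchor instead.

Classic binary morphology (erode/dilate/open/close with cross, ellipse or
rectangle structuring elements) is provided for user-defined pre-filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage

__all__ = [
    "StructuringElement",
    "ShapeKernel",
    "ShapeExtents",
    "make_structuring_element",
    "morphological_transform",
    "measure_extents",
    "validate_shape",
    "round_half_up_point",
]


@dataclass
class StructuringElement:
    """A binary neighborhood template: cross, ellipse or rectangle."""

    shape: Literal["cross", "ellipse", "rectangle"]
    matrix: np.ndarray  # (h, w) bool


@dataclass(frozen=True)
class ShapeKernel:
    """Target pixel extents (up, down, left, right) from an anchor.

    Together the X-axis pair (left, right) and Y-axis pair (up, down) define
    the expected footprint of a valid segment around its center of mass.
    """

    up: int
    down: int
    left: int
    right: int

    def __post_init__(self) -> None:
        if min(self.up, self.down, self.left, self.right) < 0:
            raise ValueError(f"extents must be non-negative: {self}")

    def to_dict(self) -> dict:
        return {"up": self.up, "down": self.down, "left": self.left, "right": self.right}

    @classmethod
    def from_dict(cls, d: dict) -> "ShapeKernel":
        return cls(up=int(d["up"]), down=int(d["down"]), left=int(d["left"]), right=int(d["right"]))


@dataclass(frozen=True)
class ShapeExtents:
    """Measured extents of a mask about an origin.

    ``clamped`` is True when the origin lies outside the mask's bounding box
    in some direction (the negative component was clamped to 0).
    """

    up: int
    down: int
    left: int
    right: int
    clamped: bool = False

    def to_dict(self) -> dict:
        return {
            "up": self.up,
            "down": self.down,
            "left": self.left,
            "right": self.right,
            "clamped": self.clamped,
        }


def make_structuring_element(
    shape: Literal["cross", "ellipse", "rectangle"], height: int, width: int
) -> StructuringElement:
    """Build a cross, inscribed-ellipse or all-ones rectangle element.

    The ellipse sets cells satisfying ((x−cx)/a)² + ((y−cy)/b)² ≤ 1 with
    a = (width−1)/2, b = (height−1)/2; degenerate axes (a or b = 0) reduce to
    a line through the center.
    """
    if height < 1 or width < 1:
        raise ValueError(f"element size must be positive, got {height}×{width}")
    cy, cx = (height - 1) // 2, (width - 1) // 2
    if shape == "rectangle":
        m = np.ones((height, width), dtype=bool)
    elif shape == "cross":
        m = np.zeros((height, width), dtype=bool)
        m[cy, :] = True
        m[:, cx] = True
    elif shape == "ellipse":
        b, a = (height - 1) / 2.0, (width - 1) / 2.0
        yy, xx = np.mgrid[0:height, 0:width].astype(np.float64)
        ty = np.where(b > 0, ((yy - b) / max(b, 1e-12)) ** 2, np.where(yy == b, 0.0, np.inf))
        tx = np.where(a > 0, ((xx - a) / max(a, 1e-12)) ** 2, np.where(xx == a, 0.0, np.inf))
        m = ty + tx <= 1.0
    else:
        raise ValueError(f"unknown element shape {shape!r}")
    return StructuringElement(shape=shape, matrix=m)


def morphological_transform(
    mask: np.ndarray,
    element: StructuringElement,
    op: Literal["erode", "dilate", "open", "close"],
) -> np.ndarray:
    """Apply a binary morphological operation with background-padded borders.

    ``open`` is erosion followed by dilation; ``close`` is dilation followed
    by erosion. Padding with background matches the semantics of operating on
    a finite-support set in an unbounded plane.
    """
    m = np.asarray(mask, dtype=bool)
    struct = element.matrix
    if not struct.any():
        raise ValueError("structuring element has no set cells")
    if op == "erode":
        return ndimage.binary_erosion(m, structure=struct, border_value=0)
    if op == "dilate":
        return ndimage.binary_dilation(m, structure=struct, border_value=0)
    if op == "open":
        eroded = morphological_transform(m, element, "erode")
        return morphological_transform(eroded, element, "dilate")
    if op == "close":
        dilated = morphological_transform(m, element, "dilate")
        return morphological_transform(dilated, element, "erode")
    raise ValueError(f"unknown operation {op!r}")


def measure_extents(
    mask: np.ndarray,
    origin: Tuple[int, int],
    mode: Literal["bbox", "ray"] = "bbox",
) -> ShapeExtents:
    """Measure a mask's pixel extents in the four cardinal directions.

    In ``bbox`` mode (default) the extents run from the origin to the mask's
    bounding box: up = origin_row − min set row, down = max set row −
    origin_row, and likewise for columns. Negative components (origin beyond
    the bounding box) are clamped to 0 and flagged. In ``ray`` mode the
    extents count contiguous set pixels marching from the origin outward.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("cannot measure extents of an empty mask")
    r0, c0 = int(origin[0]), int(origin[1])
    if not (0 <= r0 < m.shape[0] and 0 <= c0 < m.shape[1]):
        raise ValueError(f"origin {origin} outside grid {m.shape}")
    if mode == "bbox":
        rr, cc = np.nonzero(m)
        raw = (
            r0 - int(rr.min()),
            int(rr.max()) - r0,
            c0 - int(cc.min()),
            int(cc.max()) - c0,
        )
        clamped = any(x < 0 for x in raw)
        up, down, left, right = (max(0, x) for x in raw)
        return ShapeExtents(up, down, left, right, clamped)
    if mode == "ray":
        def run(dr: int, dc: int) -> int:
            n = 0
            r, c = r0 + dr, c0 + dc
            while 0 <= r < m.shape[0] and 0 <= c < m.shape[1] and m[r, c]:
                n += 1
                r += dr
                c += dc
            return n if m[r0, c0] else 0

        return ShapeExtents(run(-1, 0), run(1, 0), run(0, -1), run(0, 1), not m[r0, c0])
    raise ValueError(f"unknown measurement mode {mode!r}")


def validate_shape(
    mask: np.ndarray,
    origin: Tuple[int, int],
    target: ShapeKernel,
    tolerance: Union[int, Sequence[int]] = 0,
    mode: Literal["bbox", "ray"] = "bbox",
) -> Tuple[bool, ShapeExtents]:
    """Check a mask's measured extents against a target shape kernel.

    Valid iff |measured − target| ≤ tolerance in every direction; the
    tolerance may be a scalar or a per-direction (up, down, left, right)
    sequence. The measured extents are always returned for metadata.
    """
    measured = measure_extents(mask, origin, mode=mode)
    tol = (
        (tolerance,) * 4
        if np.isscalar(tolerance)
        else tuple(int(t) for t in tolerance)
    )
    if len(tol) != 4 or any(t < 0 for t in tol):
        raise ValueError(f"tolerance must be a scalar or 4 non-negative ints: {tolerance}")
    pairs = (
        (measured.up, target.up),
        (measured.down, target.down),
        (measured.left, target.left),
        (measured.right, target.right),
    )
    valid = all(abs(m - t) <= tl for (m, t), tl in zip(pairs, tol))
    return valid, measured


def round_half_up_point(point: Tuple[float, float]) -> Tuple[int, int]:
    """Round a real (row, col) to the nearest pixel, ties upward — the rule
    used to turn a center of mass into a validation anchor."""
    return (
        int(np.floor(point[0] + 0.5)),
        int(np.floor(point[1] + 0.5)),
    )
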