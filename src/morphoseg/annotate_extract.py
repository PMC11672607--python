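"""Segment delivery: validation, annotation, extraction and metadata.

The final stage turns labeled regions into deliverables: each region is
validated against the configured shape kernel (all pass when none is set),
valid segments are extracted from the original image in their true colors,
an optional preview is annotated with bounding squares around each center of
mass, and a JSON metadata document records every segment's geometry together
with the full run configuration, so a run can be reproduced or refined and
downstream models get precise spatial context.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Literal, Optional, Sequence, Tuple, Union

import numpy as np

from .conv_features import Region, center_of_mass
from .imaging_io import Image
from .shape_morphology import (
    ShapeExtents,
    ShapeKernel,
    measure_extents,
    round_half_up_point,
    validate_shape,
)

__all__ = [
    "SegmentRecord",
    "SegmentationResult",
    "draw_bounding_square",
    "region_bbox",
    "extract_region",
    "fulfill_segmentation",
    "build_metadata",
    "metadata_to_json",
]


@dataclass
class SegmentRecord:
    """Everything downstream consumers need to know about one segment."""

    id: int
    value: Tuple[int, ...]
    area: int
    center_of_mass: Tuple[float, float]
    extents: ShapeExtents
    bbox: Tuple[int, int, int, int]  # inclusive (min_row, min_col, max_row, max_col)
    valid: bool
    source: str = ""
    origin_in_mask: bool = True

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "value": list(self.value),
            "area": self.area,
            "center_of_mass": list(self.center_of_mass),
            "extents": self.extents.to_dict(),
            "bbox": list(self.bbox),
            "valid": self.valid,
            "source": self.source,
            "origin_in_mask": self.origin_in_mask,
        }


@dataclass
class SegmentationResult:
    """Ordered (record, extracted image) pairs for the valid segments, plus
    the optional annotated preview."""

    segments: List[Tuple[SegmentRecord, Image]]
    preview: Optional[Image] = None

    def __len__(self) -> int:
        return len(self.segments)

    def records(self) -> List[SegmentRecord]:
        return [rec for rec, _ in self.segments]


def _draw_rect_outline(
    arr: np.ndarray,
    top: int,
    left: int,
    bottom: int,
    right: int,
    color: Sequence[int],
) -> None:
    """Draw a 1-px outline of the inclusive rect, clipped to the grid."""
    h, w = arr.shape[:2]
    col = np.asarray(color[: arr.shape[2]], dtype=np.uint8)
    t, b = max(top, 0), min(bottom, h - 1)
    lf, rt = max(left, 0), min(right, w - 1)
    if t > b or lf > rt:
        return
    if 0 <= top < h:
        arr[top, lf : rt + 1] = col
    if 0 <= bottom < h:
        arr[bottom, lf : rt + 1] = col
    if 0 <= left < w:
        arr[t : b + 1, left] = col
    if 0 <= right < w:
        arr[t : b + 1, right] = col


def draw_bounding_square(
    image: Image,
    center: Tuple[int, int],
    radius: int,
    color: Tuple[int, int, int] = (255, 0, 0),
) -> Image:
    """Return a copy of the image with a square outline around ``center``.

    The square has side 2·radius+1 and stroke 1, clipped silently at the
    image borders; its interior is untouched and the input is not mutated.
    """
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    r, c = int(center[0]), int(center[1])
    if not (0 <= r < image.height and 0 <= c < image.width):
        raise ValueError(f"center {center} outside image {image.height}×{image.width}")
    out = image.copy()
    _draw_rect_outline(out.pixels, r - radius, c - radius, r + radius, c + radius, color)
    return out


def region_bbox(mask: np.ndarray) -> Tuple[int, int, int, int]:
    """Tight inclusive bounds (min_row, min_col, max_row, max_col) of the
    set pixels."""
    m = np.asarray(mask, dtype=bool)
    rr, cc = np.nonzero(m)
    if rr.size == 0:
        raise ValueError("bounding box of an empty mask is undefined")
    return int(rr.min()), int(cc.min()), int(rr.max()), int(cc.max())


def extract_region(
    original: Image,
    mask: np.ndarray,
    mode: Literal["masked_full", "cropped"] = "masked_full",
) -> Image:
    """Carve a region out of the original image in its true colors.

    Set pixels carry the original intensities bit-exactly; unset pixels are
    background (0). ``cropped`` additionally trims to the region's bounding
    box.
    """
    m = np.asarray(mask, dtype=bool)
    if m.shape != (original.height, original.width):
        raise ValueError(
            f"mask {m.shape} does not match image {(original.height, original.width)}"
        )
    if not m.any():
        raise ValueError("cannot extract an empty region")
    out = np.zeros_like(original.pixels)
    out[m] = original.pixels[m]
    if mode == "cropped":
        r0, c0, r1, c1 = region_bbox(m)
        out = out[r0 : r1 + 1, c0 : c1 + 1]
    elif mode != "masked_full":
        raise ValueError(f"unknown extraction mode {mode!r}")
    return Image(out.copy(), original.channel_order)


def _default_box_radius(record: SegmentRecord, shape_kernel: Optional[ShapeKernel]) -> int:
    if shape_kernel is not None:
        return max(shape_kernel.up, shape_kernel.down, shape_kernel.left, shape_kernel.right) + 2
    return max(1, int(np.ceil(np.sqrt(record.area)) // 2))


def fulfill_segmentation(
    original: Image,
    regions: Sequence[Region],
    shape_kernel: Optional[ShapeKernel] = None,
    include_boxes: bool = False,
    box_radius: Optional[int] = None,
    tolerance: Union[int, Sequence[int]] = 0,
    extract_mode: Literal["masked_full", "cropped"] = "masked_full",
    source: str = "",
) -> SegmentationResult:
    """Validate regions, extract the valid ones and optionally annotate.

    Each region's center of mass (rounded half-up to a pixel) anchors the
    extent measurement; with no shape kernel every region passes. Only valid
    segments yield extracted images, ordered by region label. The preview
    (drawn only when ``include_boxes``) shows a bounding square at each valid
    center of mass and, when a kernel is configured, the kernel's target
    extents rectangle; it never changes the records. An empty result is
    legal, and the whole step can be rerun with adjusted parameters.
    """
    segments: List[Tuple[SegmentRecord, Image]] = []
    preview = original.copy() if include_boxes else None
    for region in sorted(regions, key=lambda r: r.label):
        com = center_of_mass(region)
        anchor = round_half_up_point(com)
        anchor = (
            min(max(anchor[0], 0), original.height - 1),
            min(max(anchor[1], 0), original.width - 1),
        )
        if shape_kernel is None:
            extents = measure_extents(region.mask, anchor)
            valid = True
        else:
            valid, extents = validate_shape(region.mask, anchor, shape_kernel, tolerance)
        record = SegmentRecord(
            id=region.label,
            value=region.value,
            area=region.area,
            center_of_mass=com,
            extents=extents,
            bbox=region_bbox(region.mask),
            valid=valid,
            source=source,
            origin_in_mask=bool(region.mask[anchor[0], anchor[1]]),
        )
        if not valid:
            continue
        segments.append((record, extract_region(original, region.mask, extract_mode)))
        if preview is not None:
            radius = box_radius if box_radius is not None else _default_box_radius(record, shape_kernel)
            preview = draw_bounding_square(preview, anchor, radius)
            if shape_kernel is not None:
                _draw_rect_outline(
                    preview.pixels,
                    anchor[0] - shape_kernel.up,
                    anchor[1] - shape_kernel.left,
                    anchor[0] + shape_kernel.down,
                    anchor[1] + shape_kernel.right,
                    (255, 0, 0),
                )
    return SegmentationResult(segments=segments, preview=preview)


def build_metadata(records: Sequence[SegmentRecord], run_parameters: dict) -> dict:
    """Assemble the run's metadata document.

    ``{"run": {...parameters...}, "objects": [...]}`` — every segment's
    geometry plus the verbatim run configuration, so the document alone
    suffices to rerun or audit the segmentation.
    """
    doc = {
        "run": dict(run_parameters),
        "objects": [r.to_dict() for r in records],
    }
    try:
        json.dumps(doc)
    except TypeError as exc:
        raise ValueError(f"run parameters are not JSON-serializable: {exc}") from exc
    return doc


def metadata_to_json(doc: dict) -> str:
    """Serialize metadata with canonical key order (byte-stable round trip)."""
    return json.dumps(doc, sort_keys=True, indent=2) + "\n"
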