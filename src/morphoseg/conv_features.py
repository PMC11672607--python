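"""Edge-feature extraction, region isolation and centers of mass.

Directional 3×3 filters respond to intensity change across rows (horizontal
edges) and across columns (vertical edges); their magnitudes merge into one
binary edge map. Setting edge pixels to a background sentinel disconnects
adjacent regions, so plain connected-component labeling then isolates every
contiguous run of equal palette values as a candidate object, each carrying
its center of mass as an anchor for shape validation.

The filters are applied as sliding dot-products (correlation) with the
kernels below — the usual computer-vision reading of "convolution". The
Sobel kernels are antisymmetric, so true convolution would only flip the
response sign; all downstream use is magnitude-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal, Tuple, Union

import numpy as np
from scipy import ndimage
from skimage import measure

from .imaging_io import Image
from .quantize import QuantizedImage

__all__ = [
    "BACKGROUND_LABEL",
    "EDGE_KERNELS",
    "EdgeMap",
    "Region",
    "detect_edges_horizontal",
    "detect_edges_vertical",
    "merge_edge_maps",
    "zero_edge_pixels",
    "extract_regions",
    "center_of_mass",
]

#: Sentinel written into the label grid where edges were zeroed; cluster
#: indices are always >= 0 so -1 can never collide with a palette entry.
BACKGROUND_LABEL = -1

# Row-gradient kernels: respond to horizontal edges (intensity change down
# the rows). The vertical-edge kernel is the transpose.
EDGE_KERNELS = {
    "sobel": np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=np.float64),
    "difference": np.array([[-1], [0], [1]], dtype=np.float64),
}


@dataclass
class EdgeMap:
    """Merged edge structure: binary flags plus the signed directional
    responses they were derived from."""

    flags: np.ndarray  # (H, W) bool
    responses_h: np.ndarray
    responses_v: np.ndarray


@dataclass
class Region:
    """A maximal 4-connected set of equal-valued pixels.

    ``value`` is the palette color shared by the region's pixels (a tuple,
    or a scalar for single-channel input); ``center_of_mass`` is the
    unweighted mean (row, col) of its pixels.
    """

    label: int
    mask: np.ndarray  # (H, W) bool
    value: Tuple[int, ...]
    area: int
    center_of_mass: Tuple[float, float]


def _as_plane(gray: Union[Image, np.ndarray]) -> np.ndarray:
    if isinstance(gray, Image):
        if gray.channels != 1:
            raise ValueError("edge detection requires a single-channel input")
        return gray.pixels[:, :, 0].astype(np.float64)
    arr = np.asarray(gray, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"edge detection requires a 2-D grid, got shape {arr.shape}")
    return arr


def detect_edges_horizontal(
    gray: Union[Image, np.ndarray], kernel: Literal["sobel", "difference"] = "sobel"
) -> np.ndarray:
    """Signed response of the row-gradient filter (horizontal edges),
    reflected borders."""
    plane = _as_plane(gray)
    return ndimage.correlate(plane, EDGE_KERNELS[kernel], mode="reflect")


def detect_edges_vertical(
    gray: Union[Image, np.ndarray], kernel: Literal["sobel", "difference"] = "sobel"
) -> np.ndarray:
    """Signed response of the column-gradient filter (vertical edges),
    reflected borders."""
    plane = _as_plane(gray)
    return ndimage.correlate(plane, EDGE_KERNELS[kernel].T, mode="reflect")


def merge_edge_maps(
    h: np.ndarray,
    v: np.ndarray,
    threshold: float = 0.0,
    combine: Literal["abs_sum", "max", "l2"] = "abs_sum",
) -> EdgeMap:
    """Merge directional responses into one binary edge map.

    A pixel is flagged when the combined magnitude exceeds ``threshold``.
    The default combination |h| + |v| with threshold 0 flags any nonzero
    response, which on a quantized label grid marks exactly the palette
    boundaries.
    """
    h = np.asarray(h, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if h.shape != v.shape:
        raise ValueError(f"response shapes differ: {h.shape} vs {v.shape}")
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    if combine == "abs_sum":
        magnitude = np.abs(h) + np.abs(v)
    elif combine == "max":
        magnitude = np.maximum(np.abs(h), np.abs(v))
    elif combine == "l2":
        magnitude = np.hypot(h, v)
    else:
        raise ValueError(f"unknown combination {combine!r}")
    return EdgeMap(flags=magnitude > threshold, responses_h=h, responses_v=v)


def zero_edge_pixels(img: QuantizedImage, edges: EdgeMap) -> QuantizedImage:
    """Overwrite edge-flagged pixels with the background sentinel.

    Flagged pixels get color 0 and label ``BACKGROUND_LABEL``; every other
    pixel is bit-identical to the input. This disconnects regions that the
    palette alone would leave touching.
    """
    if edges.flags.shape != img.labels.shape:
        raise ValueError(
            f"edge map {edges.flags.shape} does not match image {img.labels.shape}"
        )
    out = img.copy()
    out.colors[edges.flags] = 0
    out.labels = out.labels.astype(np.int32, copy=True)
    out.labels[edges.flags] = BACKGROUND_LABEL
    return out


def extract_regions(
    img: QuantizedImage, min_area: int = 1, connectivity: int = 1
) -> List[Region]:
    """Isolate contiguous equal-valued regions of non-background pixels.

    Regions are maximal connected components (4-connected by default,
    ``connectivity=2`` for 8-connectivity) of pixels sharing one quantized
    value; components smaller than ``min_area`` are dropped. Region labels
    are assigned 1, 2, ... in raster order of each region's first pixel.
    """
    if min_area < 0:
        raise ValueError(f"min_area must be non-negative, got {min_area}")
    if connectivity not in (1, 2):
        raise ValueError(f"connectivity must be 1 (4-conn) or 2 (8-conn)")
    labels = img.labels
    comp = measure.label(labels, background=BACKGROUND_LABEL, connectivity=connectivity)
    # measure.label treats every value == background as one non-region; all
    # remaining components already split by value because equal-label
    # connectivity is what it computes.
    flat = comp.ravel()
    order_of_first = {}
    for idx, lab in enumerate(flat):
        if lab != 0 and lab not in order_of_first:
            order_of_first[lab] = idx
    regions: List[Region] = []
    next_id = 1
    for lab in sorted(order_of_first, key=order_of_first.get):
        mask = comp == lab
        area = int(mask.sum())
        if area < min_area:
            continue
        rr, cc = np.nonzero(mask)
        first = (rr[0], cc[0])
        value = img.colors[first[0], first[1]]
        value_t = tuple(int(x) for x in np.atleast_1d(value))
        regions.append(
            Region(
                label=next_id,
                mask=mask,
                value=value_t,
                area=area,
                center_of_mass=(float(rr.mean()), float(cc.mean())),
            )
        )
        next_id += 1
    return regions


def center_of_mass(region: Union[Region, np.ndarray]) -> Tuple[float, float]:
    """Unweighted mean (row, col) of a region's pixels.

    Each member pixel counts once — the anchor is the centroid of the
    region's support, independent of intensity.
    """
    mask = region.mask if isinstance(region, Region) else np.asarray(region, dtype=bool)
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        raise ValueError("center of mass of an empty mask is undefined")
    return float(rr.mean()), float(cc.mean())
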