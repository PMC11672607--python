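"""Deterministic synthetic scenes with ground truth.

Scenes emulate the structure of pasture photographs of livestock: a
textured, near-uniform background (Gaussian noise around a base color, the
stand-in for grass or sky texture) with one or more solidly pigmented blob
objects — rectangles or ellipses of known center, extents and color — plus
optional salt-and-pepper impulse noise for the median filter to remove.

Blob colors default to the low-saturation palette of real coats (black,
brown, tan, white): channel spreads are small and the median-channel values
well separated, so blob identity survives both the channel-mixing 3-D median
filter and an 8-color quantization. The spec-level invariant is that all
scene colors are pairwise at least 32 apart in L∞.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Literal, Optional, Tuple, Union

import numpy as np

from .imaging_io import Image

__all__ = [
    "BlobSpec",
    "SceneSpec",
    "GroundTruthBlob",
    "GroundTruth",
    "generate_scene",
    "add_impulse_noise",
    "scene_spec_to_dict",
    "scene_spec_from_dict",
]


@dataclass(frozen=True)
class BlobSpec:
    """One solid object: shape, anchor center, extents and color."""

    shape: Literal["rectangle", "ellipse"]
    center: Tuple[int, int]  # (row, col)
    extents: Tuple[int, int, int, int]  # (up, down, left, right)
    color: Tuple[int, int, int]


@dataclass
class SceneSpec:
    """Full description of a synthetic scene; a fixed seed reproduces it
    bit-identically."""

    height: int
    width: int
    background_color: Tuple[int, int, int] = (96, 104, 92)
    background_noise_sd: float = 6.0
    blobs: List[BlobSpec] = field(default_factory=list)
    impulse_fraction: float = 0.0
    seed: int = 0


@dataclass
class GroundTruthBlob:
    """Rendered truth for one blob: exact mask (pre-noise), centroid,
    extents about the declared center, and color."""

    mask: np.ndarray
    center: Tuple[float, float]  # centroid of the rendered mask
    extents: Tuple[int, int, int, int]
    color: Tuple[int, int, int]


@dataclass
class GroundTruth:
    blobs: List[GroundTruthBlob]
    impulse_pixels: List[Tuple[int, int]] = field(default_factory=list)


def _blob_mask(spec: BlobSpec, height: int, width: int) -> np.ndarray:
    up, down, left, right = spec.extents
    r, c = spec.center
    r0, r1 = r - up, r + down
    c0, c1 = c - left, c + right
    if r0 < 0 or c0 < 0 or r1 >= height or c1 >= width:
        raise ValueError(f"blob {spec} exceeds the {height}×{width} scene")
    mask = np.zeros((height, width), dtype=bool)
    if spec.shape == "rectangle":
        mask[r0 : r1 + 1, c0 : c1 + 1] = True
    elif spec.shape == "ellipse":
        # ellipse inscribed in the extents box, centered on the box center
        cy, cx = (r0 + r1) / 2.0, (c0 + c1) / 2.0
        b, a = (r1 - r0) / 2.0, (c1 - c0) / 2.0
        yy, xx = np.mgrid[0:height, 0:width].astype(np.float64)
        ty = ((yy - cy) / max(b, 0.5)) ** 2
        tx = ((xx - cx) / max(a, 0.5)) ** 2
        mask = ty + tx <= 1.0
    else:
        raise ValueError(f"unknown blob shape {spec.shape!r}")
    return mask


def generate_scene(spec: SceneSpec) -> Tuple[Image, GroundTruth]:
    """Render a scene and its ground truth.

    Background = base color + clipped Gaussian texture (seeded); blobs are
    painted solid in their declared colors; impulse noise (if any) is applied
    last and its pixel list recorded. Blobs must lie fully inside the image,
    be pairwise disjoint, and use colors pairwise separated by ≥ 32 in L∞
    (including against the background) so they remain separable after
    quantization.
    """
    colors = [spec.background_color] + [b.color for b in spec.blobs]
    for i in range(len(colors)):
        for j in range(i + 1, len(colors)):
            gap = max(abs(a - b) for a, b in zip(colors[i], colors[j]))
            if gap < 32:
                raise ValueError(
                    f"scene colors {colors[i]} and {colors[j]} are only {gap} apart "
                    "in L∞; need >= 32 to survive quantization"
                )
    rng = np.random.default_rng(spec.seed)
    base = np.asarray(spec.background_color, dtype=np.float64)
    canvas = base + rng.normal(0.0, spec.background_noise_sd, (spec.height, spec.width, 3))
    canvas = np.round(canvas).clip(0, 255).astype(np.uint8)
    occupied = np.zeros((spec.height, spec.width), dtype=bool)
    truth_blobs: List[GroundTruthBlob] = []
    for blob in spec.blobs:
        mask = _blob_mask(blob, spec.height, spec.width)
        if (mask & occupied).any():
            raise ValueError(f"blob {blob} overlaps a previous blob")
        occupied |= mask
        canvas[mask] = blob.color
        rr, cc = np.nonzero(mask)
        truth_blobs.append(
            GroundTruthBlob(
                mask=mask,
                center=(float(rr.mean()), float(cc.mean())),
                extents=blob.extents,
                color=blob.color,
            )
        )
    image = Image(canvas)
    impulse: List[Tuple[int, int]] = []
    if spec.impulse_fraction > 0:
        image, impulse = add_impulse_noise(
            image, spec.impulse_fraction, seed=int(rng.integers(0, 2**31))
        )
    return image, GroundTruth(blobs=truth_blobs, impulse_pixels=impulse)


def add_impulse_noise(
    image: Image, fraction: float, seed: int = 0
) -> Tuple[Image, List[Tuple[int, int]]]:
    """Corrupt a seeded uniform sample of pixels with extreme values.

    round(fraction·H·W) distinct pixels are each set, per channel, to 0 or
    255 (salt-and-pepper). Returns the noisy image and the corrupted pixel
    list.
    """
    if not (0 <= fraction < 1):
        raise ValueError(f"impulse fraction must be in [0, 1), got {fraction}")
    h, w = image.height, image.width
    n = int(round(fraction * h * w))
    out = image.copy()
    if n == 0:
        return out, []
    rng = np.random.default_rng(seed)
    flat = rng.choice(h * w, size=n, replace=False)
    rows, cols = np.divmod(flat, w)
    values = rng.integers(0, 2, size=(n, image.channels)).astype(np.uint8) * 255
    out.pixels[rows, cols] = values
    return out, [(int(r), int(c)) for r, c in zip(rows, cols)]


def scene_spec_to_dict(spec: SceneSpec) -> dict:
    return {
        "height": spec.height,
        "width": spec.width,
        "background_color": list(spec.background_color),
        "background_noise_sd": spec.background_noise_sd,
        "impulse_fraction": spec.impulse_fraction,
        "seed": spec.seed,
        "blobs": [
            {
                "shape": b.shape,
                "center": list(b.center),
                "extents": list(b.extents),
                "color": list(b.color),
            }
            for b in spec.blobs
        ],
    }


def scene_spec_from_dict(d: dict) -> SceneSpec:
    return SceneSpec(
        height=int(d["height"]),
        width=int(d["width"]),
        background_color=tuple(d.get("background_color", (96, 104, 92))),
        background_noise_sd=float(d.get("background_noise_sd", 6.0)),
        blobs=[
            BlobSpec(
                shape=b["shape"],
                center=tuple(b["center"]),
                extents=tuple(b["extents"]),
                color=tuple(b["color"]),
            )
            for b in d.get("blobs", [])
        ],
        impulse_fraction=float(d.get("impulse_fraction", 0.0)),
        seed=int(d.get("seed", 0)),
    )
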