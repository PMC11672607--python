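"""Raster image I/O and layout conversions.

The pipeline's universal currency is an 8-bit :class:`Image` — an H×W×C grid
with a declared channel order. Internally everything is RGB; BGR exists only
at the I/O boundary for interoperability with BGR-native tooling. Coordinates
are 0-based ``(row, col)`` with row 0 at the top, so "up" means decreasing
row index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
from PIL import Image as PILImage

ChannelOrder = Literal["RGB", "BGR"]

__all__ = [
    "Image",
    "PixelTable",
    "load_image",
    "save_image",
    "flatten_pixels",
    "restore_image",
    "resize_normalize",
]


@dataclass
class Image:
    """An 8-bit raster image: H×W×C uint8 grid plus channel-order tag.

    ``C`` is 1 (grayscale / single channel) or 3 (color). For single-channel
    images the channel order is irrelevant and kept as "RGB".
    """

    pixels: np.ndarray
    channel_order: ChannelOrder = "RGB"

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim == 2:
            arr = arr[:, :, np.newaxis]
        if arr.ndim != 3 or arr.shape[2] not in (1, 3):
            raise ValueError(
                f"pixels must be H×W×C with C in {{1, 3}}, got shape {arr.shape}"
            )
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("image must contain at least one pixel")
        if arr.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {arr.dtype}")
        if self.channel_order not in ("RGB", "BGR"):
            raise ValueError(f"unknown channel order {self.channel_order!r}")
        self.pixels = arr

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return self.pixels.shape[2]

    def to_order(self, order: ChannelOrder) -> "Image":
        """Return a copy in the requested channel order (identity if equal)."""
        if order == self.channel_order or self.channels == 1:
            return Image(self.pixels.copy(), order if self.channels == 3 else "RGB")
        return Image(self.pixels[:, :, ::-1].copy(), order)

    def copy(self) -> "Image":
        return Image(self.pixels.copy(), self.channel_order)


@dataclass
class PixelTable:
    """Row-major pixel table: one row per pixel, N = H·W rows of C intensities."""

    rows: np.ndarray
    source_height: int
    source_width: int

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows)
        if rows.ndim != 2:
            raise ValueError(f"rows must be 2-D, got shape {rows.shape}")
        if rows.shape[0] != self.source_height * self.source_width:
            raise ValueError(
                f"row count {rows.shape[0]} != "
                f"{self.source_height}×{self.source_width}"
            )
        self.rows = rows


def load_image(path: Union[str, Path], channel_order: ChannelOrder = "RGB") -> Image:
    """Read a PNG or JPEG file into an :class:`Image`.

    Inputs deeper than 8 bits are rescaled to 8-bit. Palette and RGBA inputs
    are converted to RGB; grayscale stays single-channel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        with PILImage.open(path) as pil:
            pil.load()
            if pil.mode in ("I", "I;16", "I;16B", "I;16L"):
                arr16 = np.asarray(pil, dtype=np.float64)
                arr = np.round(arr16 / 257.0).clip(0, 255).astype(np.uint8)
            elif pil.mode == "L":
                arr = np.asarray(pil, dtype=np.uint8)
            else:
                arr = np.asarray(pil.convert("RGB"), dtype=np.uint8)
    except (OSError, SyntaxError) as exc:
        raise ValueError(f"cannot decode {path} as PNG/JPEG: {exc}") from exc
    img = Image(arr, "RGB")
    return img.to_order(channel_order) if img.channels == 3 else img


def save_image(image: Image, path: Union[str, Path]) -> None:
    """Write an image to disk. PNG is lossless and canonical; JPEG is
    permitted for annotated previews only (it is lossy)."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    rgb = image.to_order("RGB")
    arr = rgb.pixels[:, :, 0] if rgb.channels == 1 else rgb.pixels
    PILImage.fromarray(arr).save(path)


def flatten_pixels(image: Image) -> PixelTable:
    """Reshape the H×W×C grid into an N×C table in row-major scan order."""
    h, w, c = image.pixels.shape
    return PixelTable(image.pixels.reshape(h * w, c).copy(), h, w)


def restore_image(table: PixelTable, height: int, width: int) -> Image:
    """Row-major inverse of :func:`flatten_pixels`."""
    rows = np.asarray(table.rows)
    if rows.shape[0] != height * width:
        raise ValueError(
            f"cannot restore {rows.shape[0]} pixels to {height}×{width}"
        )
    arr = rows.reshape(height, width, rows.shape[1])
    if arr.dtype != np.uint8:
        arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    return Image(arr.copy())


def resize_normalize(image: Image, max_dimension: Optional[int] = None) -> Image:
    """Standardize resolution and dynamic range.

    If ``max_dimension`` is set and the longest side exceeds it, the image is
    rescaled (bilinear) so the longest side equals ``max_dimension``,
    preserving aspect ratio. Intensities are then min-max rescaled to span
    [0, 255] when the dynamic range is not already full; constant images are
    left unchanged (zero dynamic range is guarded).
    """
    if max_dimension is not None and max_dimension < 1:
        raise ValueError(f"max_dimension must be >= 1, got {max_dimension}")
    arr = image.pixels
    h, w = arr.shape[:2]
    if max_dimension is not None and max(h, w) > max_dimension:
        scale = max_dimension / max(h, w)
        new_h = max(1, round(h * scale))
        new_w = max(1, round(w * scale))
        if max(h, w) == h:
            new_h = max_dimension
        else:
            new_w = max_dimension
        plane = arr[:, :, 0] if arr.shape[2] == 1 else arr
        pil = PILImage.fromarray(plane)
        resized = np.asarray(
            pil.resize((new_w, new_h), PILImage.Resampling.BILINEAR), dtype=np.uint8
        )
        if resized.ndim == 2:
            resized = resized[:, :, np.newaxis]
        arr = resized
    lo, hi = int(arr.min()), int(arr.max())
    if hi > lo and (lo > 0 or hi < 255):
        stretched = (arr.astype(np.float64) - lo) * (255.0 / (hi - lo))
        arr = np.round(stretched).clip(0, 255).astype(np.uint8)
    return Image(arr.copy(), image.channel_order)
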