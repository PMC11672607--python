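"""Palette reduction by k-means color quantization.

The image is flattened to a pixel table, a k-means model is fit on the pixel
colors, every pixel is relabeled to its nearest centroid, the image is
rebuilt at its original dimensions from the rounded centroid colors, and the
result is widened to 32-bit unsigned integers. The default palette size is
k = 8.

Centroids are kept real-valued inside the model and rounded (half-up) only
when an image is reconstructed. "Uint32" output is a per-channel widening
cast of the 8-bit palette, not a bit-packing; :func:`pack_rgb` provides the
packed single-integer view (R·2¹⁶ + G·2⁸ + B) for single-channel
convolution.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .imaging_io import Image, PixelTable, flatten_pixels

logger = logging.getLogger(__name__)

__all__ = [
    "QuantizerModel",
    "QuantizedImage",
    "fit_quantizer",
    "assign_labels",
    "quantize_image",
    "pack_rgb",
    "model_to_json",
    "model_from_json",
]


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # np.round ties to even; palette colors round .5 upward.
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


@dataclass
class QuantizerModel:
    """A fitted k-color palette: cluster count, centroids and the fit seed."""

    k: int
    centroids: Optional[np.ndarray] = None  # (k, C) float64, None until fit
    seed: int = 0

    @property
    def is_fit(self) -> bool:
        return self.centroids is not None

    def palette(self) -> np.ndarray:
        """Centroids rounded half-up to integer colors, shape (k, C)."""
        if not self.is_fit:
            raise RuntimeError("quantizer model has not been fit")
        return _round_half_up(self.centroids).astype(np.uint32)


@dataclass
class QuantizedImage:
    """Palette-reduced image: uint32 colors plus per-pixel cluster labels.

    ``labels`` is signed so downstream stages can overwrite pixels with the
    background sentinel (-1) without colliding with cluster index 0.
    """

    colors: np.ndarray  # (H, W, C) uint32
    labels: np.ndarray  # (H, W) int32

    def __post_init__(self) -> None:
        if self.colors.shape[:2] != self.labels.shape:
            raise ValueError(
                f"colors {self.colors.shape} and labels {self.labels.shape} disagree"
            )

    @property
    def height(self) -> int:
        return self.colors.shape[0]

    @property
    def width(self) -> int:
        return self.colors.shape[1]

    def copy(self) -> "QuantizedImage":
        return QuantizedImage(self.colors.copy(), self.labels.copy())


def fit_quantizer(pixels: PixelTable, k: int = 8, seed: int = 0) -> QuantizerModel:
    """Fit a k-means color model on a pixel table.

    Standard iterative refinement with k-means++ seeding; a fixed seed makes
    the fit reproducible. Requires at least k pixels. When the data hold
    fewer than k distinct colors the fit degenerates to duplicate centroids;
    the model is still returned, with a logged warning.
    """
    if k < 1:
        raise ValueError(f"cluster count k must be >= 1, got {k}")
    rows = np.asarray(pixels.rows, dtype=np.float64)
    if rows.shape[0] < k:
        raise ValueError(f"need at least k={k} pixels, got {rows.shape[0]}")
    n_distinct = np.unique(rows, axis=0).shape[0]
    if n_distinct < k:
        logger.warning(
            "only %d distinct colors for k=%d clusters; centroids will degenerate",
            n_distinct,
            k,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns on the degenerate case
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(rows)
    return QuantizerModel(k=k, centroids=km.cluster_centers_.astype(np.float64), seed=seed)


def assign_labels(model: QuantizerModel, pixels: PixelTable) -> np.ndarray:
    """Label every pixel with the index of its Euclidean-nearest centroid.

    Ties are broken by the lowest centroid index. Implemented as an explicit
    distance scan (rather than the fit object's predictor) so the tie-break
    is guaranteed.
    """
    if not model.is_fit:
        raise RuntimeError("quantizer model has not been fit")
    rows = np.asarray(pixels.rows, dtype=np.float64)
    if rows.shape[1] != model.centroids.shape[1]:
        raise ValueError(
            f"pixel dimensionality {rows.shape[1]} != "
            f"centroid dimensionality {model.centroids.shape[1]}"
        )
    d2 = cdist(rows, model.centroids, metric="sqeuclidean")
    return np.argmin(d2, axis=1).astype(np.int32)


def quantize_image(
    image: Union[Image, QuantizedImage], model: QuantizerModel
) -> QuantizedImage:
    """Map every pixel to its nearest palette color.

    Flatten → assign labels → replace each pixel by its rounded centroid →
    rebuild at the original dimensions → cast to uint32. The output holds at
    most k distinct colors and is idempotent under re-quantization with the
    same model.
    """
    if not model.is_fit:
        raise RuntimeError("quantizer model has not been fit")
    if isinstance(image, QuantizedImage):
        arr = image.colors.astype(np.float64)
        h, w, c = arr.shape
        rows = arr.reshape(h * w, c)
        table = PixelTable(rows, h, w)
    else:
        table = flatten_pixels(image)
        h, w = image.height, image.width
    labels = assign_labels(model, table)
    palette = model.palette()
    colors = palette[labels].reshape(h, w, palette.shape[1]).astype(np.uint32)
    return QuantizedImage(colors, labels.reshape(h, w))


def pack_rgb(colors: np.ndarray) -> np.ndarray:
    """Pack an H×W×3 color grid into a single-channel uint32 grid
    (R·2¹⁶ + G·2⁸ + B), a compact input for single-channel convolution."""
    arr = np.asarray(colors, dtype=np.uint32)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected H×W×3 colors, got shape {arr.shape}")
    return (arr[:, :, 0] << 16) | (arr[:, :, 1] << 8) | arr[:, :, 2]


def model_to_json(model: QuantizerModel, path: Optional[Union[str, Path]] = None) -> str:
    """Serialize a fitted model (k, centroids, seed) to JSON."""
    if not model.is_fit:
        raise RuntimeError("quantizer model has not been fit")
    doc = {
        "k": model.k,
        "centroids": model.centroids.tolist(),
        "seed": model.seed,
    }
    text = json.dumps(doc, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def model_from_json(source: Union[str, Path]) -> QuantizerModel:
    """Inverse of :func:`model_to_json`; accepts a JSON string or a path."""
    if isinstance(source, Path):
        text = source.read_text()
    elif source.lstrip().startswith("{"):
        text = source
    else:
        text = Path(source).read_text()
    doc = json.loads(text)
    return QuantizerModel(
        k=int(doc["k"]),
        centroids=np.asarray(doc["centroids"], dtype=np.float64),
        seed=int(doc["seed"]),
    )
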