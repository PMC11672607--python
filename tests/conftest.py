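"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library code paths they check:
median filtering by exhaustive neighborhood sort, region isolation by
recursive flood fill, nearest-centroid assignment by an explicit distance
table.
"""

from itertools import product

import numpy as np
import pytest

from morphoseg import Image


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def random_image(rng):
    def make(h=9, w=9, c=3, lo=0, hi=256):
        return Image(rng.integers(lo, hi, size=(h, w, c), dtype=np.uint8))

    return make


def median_oracle(arr: np.ndarray, kernel) -> np.ndarray:
    """Exhaustive neighborhood-sort median with symmetric (reflect-including-
    edge) borders, matching the filter's stated border rule."""
    kh, kw, kc = kernel
    ph, pw, pc = kh // 2, kw // 2, kc // 2
    padded = np.pad(arr, ((ph, ph), (pw, pw), (pc, pc)), mode="symmetric")
    out = np.empty_like(arr)
    h, w, c = arr.shape
    mid = (kh * kw * kc) // 2
    for i, j, k in product(range(h), range(w), range(c)):
        block = padded[i : i + kh, j : j + kw, k : k + kc]
        out[i, j, k] = np.sort(block, axis=None)[mid]
    return out


def flood_fill_partition(labels: np.ndarray, background: int, connectivity: int = 1):
    """Stack-based flood fill; returns masks of equal-valued components in
    raster order of their first pixel."""
    h, w = labels.shape
    seen = np.zeros((h, w), dtype=bool)
    if connectivity == 1:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    masks = []
    for r0 in range(h):
        for c0 in range(w):
            if seen[r0, c0] or labels[r0, c0] == background:
                continue
            value = labels[r0, c0]
            mask = np.zeros((h, w), dtype=bool)
            stack = [(r0, c0)]
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                mask[r, c] = True
                for dr, dc in steps:
                    rr, cc = r + dr, c + dc
                    if (
                        0 <= rr < h
                        and 0 <= cc < w
                        and not seen[rr, cc]
                        and labels[rr, cc] == value
                    ):
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            masks.append((mask, value))
    return masks


def nearest_centroid_oracle(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Exhaustive nearest-centroid scan with lowest-index tie-break."""
    out = np.empty(points.shape[0], dtype=int)
    for i, p in enumerate(points):
        best, best_d = 0, None
        for j, c in enumerate(centroids):
            d = float(np.sum((p - c) ** 2))
            if best_d is None or d < best_d:
                best, best_d = j, d
        out[i] = best
    return out
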