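"""Noise suppression and channel reduction.

A 3-D median filter runs over (rows, cols, channels) jointly, so a single
order statistic spans all color channels of the neighborhood — this
suppresses impulse noise consistently across channels instead of filtering
each plane in isolation. The default kernel (5, 5, 5) matches the smallest
feature size the downstream stages are expected to keep; smaller features of
interest call for a smaller kernel.

Channel reduction keeps the single most informative channel: by default the
channel with the greatest total intensity ("dominant"), or a fixed index for
reproducibility.
"""

from __future__ import annotations

from typing import Literal, Optional, Tuple

import numpy as np
from scipy import ndimage

from .imaging_io import Image

__all__ = ["median_filter_3d", "to_single_channel"]


def median_filter_3d(
    image: Image, kernel: Tuple[int, int, int] = (5, 5, 5)
) -> Image:
    """Median-filter the image over a (rows, cols, channels) neighborhood.

    Borders are handled by reflection (the edge sample is included in the
    reflected run, so a 3-channel image supports a 5-tap channel axis). Every
    kernel entry must be odd so the median is an exact order statistic of the
    neighborhood. Single-channel images use a (k, k, 1) kernel.
    """
    if len(kernel) != 3:
        raise ValueError(f"kernel must have 3 entries, got {kernel}")
    if any(k < 1 or k % 2 == 0 for k in kernel):
        raise ValueError(f"kernel entries must be odd and >= 1, got {kernel}")
    size = kernel if image.channels == 3 else (kernel[0], kernel[1], 1)
    out = ndimage.median_filter(image.pixels, size=size, mode="reflect")
    return Image(out, image.channel_order)


def to_single_channel(
    image: Image,
    strategy: Literal["dominant_sum", "fixed"] = "dominant_sum",
    index: Optional[int] = None,
) -> Image:
    """Reduce a 3-channel image to its most prominent single channel.

    ``dominant_sum`` picks the channel with maximal total intensity (ties
    broken by lowest channel index); ``fixed`` returns channel ``index``
    verbatim. The output is always an exact sub-grid of the input.
    """
    if image.channels != 3:
        raise ValueError("to_single_channel requires a 3-channel image")
    if strategy == "dominant_sum":
        sums = image.pixels.reshape(-1, 3).sum(axis=0, dtype=np.int64)
        chosen = int(np.argmax(sums))
    elif strategy == "fixed":
        if index not in (0, 1, 2):
            raise ValueError(f"fixed channel index must be in {{0,1,2}}, got {index}")
        chosen = index
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return Image(image.pixels[:, :, chosen : chosen + 1].copy())
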