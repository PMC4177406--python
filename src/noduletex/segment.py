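"""ROI cleanup: gray-level seeded region growing.

The rectangular crop around a nodule contains background structures (muscle,
vessels); region growing from a bright seed inside the nodule removes them.
Two homogeneity criteria are provided:

* ``adaptive`` (default): a pixel joins if its gray value differs from the
  running region mean by at most ``tolerance``;
* ``fixed``: a pixel joins if it differs from the *seed* value by at most
  ``tolerance`` — equivalent to a flood fill of a fixed gray-level band,
  which makes an exact brute-force oracle possible and is monotone in the
  tolerance.

Growth is 4-connected with a FIFO queue in row-major seeding order, so the
result is deterministic.
"""

from __future__ import annotations

from collections import deque
from dataclasses import replace
from typing import Tuple

import numpy as np

from noduletex.synthetic import RoiImage

__all__ = ["region_grow", "clean_roi"]

_NEIGHBOURS = ((-1, 0), (1, 0), (0, -1), (0, 1))


def region_grow(pixels: np.ndarray, seed: Tuple[int, int], tolerance: float,
                mode: str = "adaptive") -> np.ndarray:
    """Grow a 4-connected region from ``seed``; returns a boolean mask."""
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 2 or pixels.size == 0:
        raise ValueError("expected a non-empty 2-D array")
    nr, nc = pixels.shape
    sr, sc = int(seed[0]), int(seed[1])
    if not (0 <= sr < nr and 0 <= sc < nc):
        raise ValueError(f"seed {seed} outside image bounds {pixels.shape}")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if mode not in ("adaptive", "fixed"):
        raise ValueError(f"unknown growth mode {mode!r}")

    mask = np.zeros(pixels.shape, dtype=bool)
    mask[sr, sc] = True
    queue = deque([(sr, sc)])
    total = pixels[sr, sc]
    count = 1
    seed_val = pixels[sr, sc]
    while queue:
        r, c = queue.popleft()
        for dr, dc in _NEIGHBOURS:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < nr and 0 <= cc < nc) or mask[rr, cc]:
                continue
            ref = seed_val if mode == "fixed" else total / count
            if abs(pixels[rr, cc] - ref) <= tolerance:
                mask[rr, cc] = True
                queue.append((rr, cc))
                total += pixels[rr, cc]
                count += 1
    return mask


def _central_seed(pixels: np.ndarray) -> Tuple[int, int]:
    """Brightest pixel inside the central 25% window (half-size square)."""
    nr, nc = pixels.shape
    r0, r1 = nr // 4, nr - nr // 4
    c0, c1 = nc // 4, nc - nc // 4
    window = pixels[r0:r1, c0:c1]
    flat = int(np.argmax(window))
    return r0 + flat // window.shape[1], c0 + flat % window.shape[1]


def clean_roi(roi: RoiImage, tolerance: float = 30.0,
              mode: str = "adaptive", min_pixels: int = 9) -> RoiImage:
    """Segment the nodule and zero the background.

    The seed is the brightest pixel in the central 25% window.  The crop
    stays rectangular (the transform consumes rectangles); background
    pixels are set to 0 and the mask is stored on the returned ROI.
    Raises if the grown region is degenerate (< ``min_pixels``), which
    signals segmentation failure on e.g. an all-background crop.
    """
    pixels = np.asarray(roi.pixels, dtype=float)
    if pixels.size == 0:
        raise ValueError("empty image")
    seed = _central_seed(pixels)
    mask = region_grow(pixels, seed, tolerance, mode=mode)
    if int(mask.sum()) < min_pixels:
        raise ValueError(
            f"segmentation failure: region collapsed to {int(mask.sum())} "
            f"pixels (< {min_pixels})")
    cleaned = np.where(mask, pixels, 0.0)
    return replace(roi, pixels=cleaned, mask=mask)
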