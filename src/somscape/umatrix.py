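"""U-Matrix heights and grayscale rendering of the trained map.

The U-height of a neuron is the mean Euclidean distance between its weight
vector and those of its lattice neighbors (8-neighborhood, fewer at the
borders).  Low heights mark plateaus of similar neurons — candidate
clusters — and high heights form the "walls" between them.  Rendering
follows the usual convention: similar regions light, boundaries dark.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .exceptions import OutputError
from .som import Lattice

__all__ = ["UMatrix", "compute_umatrix", "render_umatrix", "save_image"]

_NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class UMatrix:
    heights: np.ndarray  # (rows, cols), nonnegative
    rows: int
    cols: int


def compute_umatrix(lattice: Lattice) -> UMatrix:
    """Per-neuron mean weight-distance to the 8-neighborhood.

    The image has the same shape as the lattice, so segmentation labels map
    one-to-one onto neurons (and hence onto the patterns they attract).
    """
    W = lattice.weights
    rows, cols = lattice.rows, lattice.cols
    total = np.zeros((rows, cols))
    count = np.zeros((rows, cols))
    for dr, dc in _NEIGHBORS8:
        r0, r1 = max(0, -dr), rows - max(0, dr)
        c0, c1 = max(0, -dc), cols - max(0, dc)
        a = W[r0:r1, c0:c1]
        b = W[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        total[r0:r1, c0:c1] += np.linalg.norm(a - b, axis=2)
        count[r0:r1, c0:c1] += 1
    return UMatrix(heights=total / count, rows=rows, cols=cols)


def render_umatrix(um: UMatrix, invert: bool = True) -> np.ndarray:
    """Min-max normalize heights into a [0, 1] grayscale image.

    With ``invert`` on (default), low dissimilarity renders light and the
    cluster boundaries dark.  Constant heights render uniformly light.
    """
    h = um.heights
    lo, hi = float(h.min()), float(h.max())
    if hi == lo:
        norm = np.zeros_like(h)
    else:
        norm = (h - lo) / (hi - lo)
    return 1.0 - norm if invert else norm


def save_image(image: np.ndarray, path) -> None:
    """Write a [0, 1] grayscale image as an 8-bit PNG (round-half-even)."""
    q = np.rint(np.clip(image, 0.0, 1.0) * 255.0).astype(np.uint8)
    try:
        Image.fromarray(q, mode="L").save(path, format="PNG")
    except OSError as exc:
        raise OutputError(f"cannot write image to {path}: {exc}") from exc
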