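"""Cluster extraction from the U-Matrix image.

Two image-processing steps turn the rendered map into a partition: a Canny
edge pass traces the dark dissimilarity ridges that separate plateaus, and
a region-growing pass flood-fills the non-edge cells into disjoint labelled
regions.  Patterns are then assigned to the region holding their best
matching unit, which yields the cluster report.

The Canny pass runs on the *dissimilarity* field (1 - rendered image), so
cluster boundaries are gradient maxima.  Its four free parameters — blur
sigma, blur kernel radius, and the two hysteresis thresholds (normalized to
the maximum gradient magnitude) — are exposed to the user so segmentation
can be re-tuned without retraining the map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import ValidationError
from .io import ClusterReport
from .som import Lattice, TrainedSOM

__all__ = [
    "CannyParams",
    "EdgeMask",
    "LabelMap",
    "canny_edges",
    "region_growing",
    "assign_clusters",
    "query_region",
    "render_labelmap",
]

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class CannyParams:
    """The four user-tunable edge-detection parameters.

    smooth_sigma : Gaussian blur standard deviation in pixels.
    kernel_radius : half-width of the truncated blur kernel in pixels.
    low_threshold, high_threshold : hysteresis thresholds as fractions of
        the maximum gradient magnitude, in [0, 1].
    """

    smooth_sigma: float = 1.0
    kernel_radius: int = 2
    low_threshold: float = 0.1
    high_threshold: float = 0.3

    def __post_init__(self):
        if not self.smooth_sigma > 0:
            raise ValidationError("smooth_sigma must be positive")
        if self.kernel_radius < 1:
            raise ValidationError("kernel_radius must be >= 1")
        if not (0 <= self.low_threshold <= self.high_threshold <= 1):
            raise ValidationError("need 0 <= low_threshold <= high_threshold <= 1")


@dataclass
class EdgeMask:
    mask: np.ndarray  # bool, True = boundary pixel


@dataclass
class LabelMap:
    labels: np.ndarray  # int, 0 = edge/unlabeled, 1..n_regions = region
    n_regions: int


def _gaussian_kernel1d(sigma: float, radius: int) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-(x * x) / (2.0 * sigma * sigma))
    return k / k.sum()


def canny_edges(image: np.ndarray, params: CannyParams | None = None) -> EdgeMask:
    """Trace boundary ridges in a [0, 1] grayscale map image.

    Pipeline: truncated Gaussian blur (reflect borders) -> Sobel gradients
    -> non-maximum suppression with the gradient direction quantized to
    {0, 45, 90, 135} degrees -> two-threshold hysteresis (strong pixels kept,
    weak pixels kept when 8-connected to a strong one).  The input is
    inverted first so that dark boundaries become maxima.
    """
    if params is None:
        params = CannyParams()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValidationError("image must be 2-dimensional")
    if img.min() < 0 or img.max() > 1:
        raise ValidationError("image values must lie in [0, 1]")

    field = 1.0 - img  # dissimilarity: boundaries are high
    kernel = _gaussian_kernel1d(params.smooth_sigma, params.kernel_radius)
    sm = ndimage.correlate1d(field, kernel, axis=0, mode="reflect")
    sm = ndimage.correlate1d(sm, kernel, axis=1, mode="reflect")
    gy = ndimage.sobel(sm, axis=0, mode="reflect")
    gx = ndimage.sobel(sm, axis=1, mode="reflect")
    mag = np.hypot(gx, gy)
    mag_max = float(mag.max())
    rows, cols = img.shape
    if mag_max == 0.0:
        return EdgeMask(mask=np.zeros((rows, cols), dtype=bool))

    # non-maximum suppression along the quantized gradient direction
    angle = np.degrees(np.arctan2(gy, gx)) % 180.0
    bins = np.zeros(angle.shape, dtype=int)  # 0 deg
    bins[(angle >= 22.5) & (angle < 67.5)] = 1  # 45 deg
    bins[(angle >= 67.5) & (angle < 112.5)] = 2  # 90 deg
    bins[(angle >= 112.5) & (angle < 157.5)] = 3  # 135 deg
    pad = np.pad(mag, 1, mode="constant", constant_values=0.0)
    offsets = {0: (0, 1), 1: (1, 1), 2: (1, 0), 3: (1, -1)}
    n1 = np.empty_like(mag)
    n2 = np.empty_like(mag)
    for b, (dr, dc) in offsets.items():
        sel = bins == b
        n1[sel] = pad[1 + dr : 1 + dr + rows, 1 + dc : 1 + dc + cols][sel]
        n2[sel] = pad[1 - dr : 1 - dr + rows, 1 - dc : 1 - dc + cols][sel]
    # strict comparison on the positive-direction side breaks plateau ties,
    # so a perfectly symmetric two-pixel ridge thins to a single line
    nms = np.where((mag > n1) & (mag >= n2), mag, 0.0)

    # hysteresis on thresholds relative to the maximum gradient magnitude
    weak = nms >= params.low_threshold * mag_max
    strong = nms >= params.high_threshold * mag_max
    if not strong.any():
        return EdgeMask(mask=np.zeros((rows, cols), dtype=bool))
    comp, _ = ndimage.label(weak, structure=_STRUCT8)
    keep = np.unique(comp[strong])
    mask = weak & np.isin(comp, keep[keep > 0])
    return EdgeMask(mask=mask)


def region_growing(mask: EdgeMask, min_region_size: int = 2) -> LabelMap:
    """Flood-fill 4-connected non-edge components into labelled regions.

    Regions are numbered 1..n in order of their first row-major pixel;
    components smaller than ``min_region_size`` are demoted to label 0.
    """
    m = np.asarray(mask.mask, dtype=bool)
    raw, n_raw = ndimage.label(~m, structure=_STRUCT4)
    if n_raw == 0:
        return LabelMap(labels=np.zeros(m.shape, dtype=int), n_regions=0)
    flat = raw.ravel()
    # order labels by first row-major occurrence, drop undersized components
    first_seen: dict = {}
    for idx, lab in enumerate(flat):
        if lab > 0 and lab not in first_seen:
            first_seen[lab] = idx
            if len(first_seen) == n_raw:
                break
    sizes = np.bincount(flat, minlength=n_raw + 1)
    order = sorted(first_seen, key=first_seen.get)
    remap = np.zeros(n_raw + 1, dtype=int)
    next_label = 1
    for lab in order:
        if sizes[lab] >= min_region_size:
            remap[lab] = next_label
            next_label += 1
    return LabelMap(labels=remap[raw], n_regions=next_label - 1)


def _region_mean_weights(labelmap: LabelMap, lattice: Lattice) -> dict:
    means = {}
    for lab in range(1, labelmap.n_regions + 1):
        sel = labelmap.labels == lab
        means[lab] = lattice.weights[sel].mean(axis=0)
    return means


def assign_clusters(
    labelmap: LabelMap,
    trained: TrainedSOM,
    lattice: Lattice,
    pattern_ids,
) -> ClusterReport:
    """Map every pattern to the region of its best matching unit.

    A pattern whose BMU fell on an edge (or demoted) cell is reassigned to
    the nearby region whose mean neuron weight is closest to the pattern's
    fingerprint; the search radius grows by one cell at a time until a
    labelled cell appears, so no pattern is left unassigned.  Clusters are
    relabelled 1..m by decreasing size (ties by region discovery order) and
    keep the input pattern order internally.
    """
    labels_img = labelmap.labels
    if labels_img.shape != (lattice.rows, lattice.cols):
        raise ValidationError(
            f"label map shape {labels_img.shape} != lattice shape ({lattice.rows}, {lattice.cols})"
        )
    n = len(pattern_ids)
    if trained.bmu_of_pattern.shape[0] != n:
        raise ValidationError(
            f"{n} pattern ids but {trained.bmu_of_pattern.shape[0]} BMU records"
        )
    means = _region_mean_weights(labelmap, lattice)
    rows, cols = labels_img.shape
    fp = trained.fingerprints.vectors if trained.fingerprints is not None else None

    assigned = np.zeros(n, dtype=int)
    for i in range(n):
        r, c = int(trained.bmu_of_pattern[i, 0]), int(trained.bmu_of_pattern[i, 1])
        lab = int(labels_img[r, c])
        if lab == 0 and labelmap.n_regions > 0:
            # pattern's own vector, or its BMU weight when fingerprints absent
            x = fp[i] if fp is not None else lattice.weights[r, c]
            for radius in range(1, max(rows, cols)):
                r0, r1 = max(0, r - radius), min(rows, r + radius + 1)
                c0, c1 = max(0, c - radius), min(cols, c + radius + 1)
                nearby = np.unique(labels_img[r0:r1, c0:c1])
                nearby = nearby[nearby > 0]
                if nearby.size:
                    lab = int(min(nearby, key=lambda l: (np.linalg.norm(x - means[l]), l)))
                    break
        assigned[i] = lab

    members: dict = {}
    for i in range(n):
        members.setdefault(int(assigned[i]), []).append(pattern_ids[i])
    unassigned = members.pop(0, [])
    by_size = sorted(members, key=lambda lab: (-len(members[lab]), lab))
    clusters = {new: members[old] for new, old in enumerate(by_size, start=1)}
    return ClusterReport(clusters=clusters, unassigned=unassigned)


def query_region(labelmap: LabelMap, cells, trained: TrainedSOM, pattern_ids) -> list:
    """Ids of patterns whose BMU lies in the given cell set, in input order."""
    rows, cols = labelmap.labels.shape
    cellset = set()
    for r, c in cells:
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValidationError(f"cell ({r}, {c}) outside the {rows}x{cols} map")
        cellset.add((int(r), int(c)))
    out = []
    for i, pid in enumerate(pattern_ids):
        if (int(trained.bmu_of_pattern[i, 0]), int(trained.bmu_of_pattern[i, 1])) in cellset:
            out.append(pid)
    return out


def render_labelmap(labelmap: LabelMap) -> np.ndarray:
    """Grayscale [0, 1] image of the segmentation: edges black, regions in
    cycling gray levels."""
    labels = labelmap.labels
    img = np.zeros(labels.shape, dtype=float)
    for lab in range(1, labelmap.n_regions + 1):
        img[labels == lab] = 0.35 + 0.6 * (((lab - 1) * 5) % 8) / 7.0
    return img
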