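"""Synthetic inputs with the statistical structure the pipeline assumes.

Two generators cover the two kinds of real input the pipeline sees:

* :func:`make_gaussian_blobs` — dense numeric tables with a known cluster
  structure: isotropic unit-variance Gaussian clouds around centers placed
  at a controllable mutual distance, so "separation" is measured in units
  of the noise scale.
* :func:`make_fragment_matrix` — sparse binary fragment-occurrence tables
  of the kind a frequent-subgraph miner emits for molecular compounds:
  each cluster of compounds shares a signature block of fragments that its
  members carry with high probability, on top of a low background rate.

Both return the ground-truth labels alongside the matrix, so recovery can
be scored with external cluster indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import GenerationError, ValidationError
from .io import FeatureMatrix

__all__ = ["SyntheticTruth", "make_gaussian_blobs", "make_fragment_matrix"]

_MAX_CENTER_RESAMPLES = 1000


@dataclass
class SyntheticTruth:
    """A generated feature matrix plus its ground-truth cluster labels."""

    matrix: FeatureMatrix
    true_labels: np.ndarray  # (n_patterns,) int, 1..n_clusters
    params: dict


def _ids(prefix: str, n: int) -> list:
    return [f"{prefix}{i + 1}" for i in range(n)]


def make_gaussian_blobs(
    n_clusters: int = 4,
    dim: int = 8,
    n_per_cluster: int = 30,
    separation: float = 10.0,
    seed: int = 0,
) -> SyntheticTruth:
    """Isotropic Gaussian clusters around well-separated centers.

    Centers are drawn on the radius-``separation`` hypersphere and
    rejection-resampled until all mutual distances reach ``separation``;
    each pattern is its center plus standard-normal noise.  Deterministic
    per seed.
    """
    if n_clusters < 1 or dim < 2 or n_per_cluster < 1 or separation < 0:
        raise ValidationError("need n_clusters >= 1, dim >= 2, n_per_cluster >= 1, separation >= 0")
    rng = np.random.default_rng(seed)
    centers = np.zeros((n_clusters, dim))
    for g in range(n_clusters):
        for attempt in range(_MAX_CENTER_RESAMPLES + 1):
            if attempt == _MAX_CENTER_RESAMPLES:
                raise GenerationError(
                    f"could not place {n_clusters} centers at separation {separation} "
                    f"in {dim} dimensions after {_MAX_CENTER_RESAMPLES} resamples"
                )
            v = rng.standard_normal(dim)
            norm = np.linalg.norm(v)
            if norm == 0:
                continue
            cand = separation * v / norm
            if all(np.linalg.norm(cand - centers[j]) >= separation for j in range(g)):
                centers[g] = cand
                break
    n = n_clusters * n_per_cluster
    labels = np.repeat(np.arange(1, n_clusters + 1), n_per_cluster)
    patterns = centers[labels - 1] + rng.standard_normal((n, dim))
    matrix = FeatureMatrix(patterns.T, _ids("f", dim), _ids("c", n))
    return SyntheticTruth(
        matrix=matrix,
        true_labels=labels,
        params=dict(
            n_clusters=n_clusters,
            dim=dim,
            n_per_cluster=n_per_cluster,
            separation=separation,
            noise=1.0,
            seed=seed,
        ),
    )


def make_fragment_matrix(
    n_compounds: int = 60,
    n_fragments: int = 120,
    n_clusters: int = 3,
    within_prob: float = 0.8,
    background_prob: float = 0.05,
    seed: int = 0,
) -> SyntheticTruth:
    """Binary fragment x compound occurrence matrix with block structure.

    Fragments are split into one signature block per cluster plus a shared
    pool; a compound in cluster g carries each signature-g fragment with
    probability ``within_prob`` and every other fragment with
    ``background_prob``.
    """
    if not (0 <= background_prob < within_prob <= 1):
        raise ValidationError("need 0 <= background_prob < within_prob <= 1")
    if n_clusters < 1 or n_compounds < n_clusters or n_fragments < n_clusters:
        raise ValidationError("need at least one compound and one fragment per cluster")
    rng = np.random.default_rng(seed)
    block = n_fragments // (n_clusters + 1)
    if block == 0:
        block = 1
    labels = 1 + (np.arange(n_compounds) * n_clusters) // n_compounds
    # fragment f belongs to signature block (f // block) while f < n_clusters*block
    frag_block = np.minimum(np.arange(n_fragments) // block, n_clusters)  # n_clusters = shared pool
    prob = np.where(
        frag_block[:, None] == (labels[None, :] - 1), within_prob, background_prob
    )
    values = (rng.random((n_fragments, n_compounds)) < prob).astype(float)
    matrix = FeatureMatrix(values, _ids("frag", n_fragments), _ids("c", n_compounds))
    return SyntheticTruth(
        matrix=matrix,
        true_labels=labels,
        params=dict(
            n_compounds=n_compounds,
            n_fragments=n_fragments,
            n_clusters=n_clusters,
            within_prob=within_prob,
            background_prob=background_prob,
            seed=seed,
        ),
    )
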