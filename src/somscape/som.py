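"""FLSOM: batch self-organizing-map training with annealed adaptive learning.

The map is an *emergent* SOM — a planar rectangular lattice with many more
neurons than input patterns — trained by the batch rule with a Gaussian
neighborhood on the grid.  The lattice is imprinted linearly from the top
two singular directions of the data, so training starts from an ordered,
data-aligned configuration instead of random noise.

A simulated-annealing heuristic drives the schedule: the quantization error
(QE, the mean Euclidean distance from each pattern to its best matching
unit) plays the role of the temperature, and its change between consecutive
epochs adapts the neighborhood radius and the learning factor.  Training
stops when |dQE| falls below a user threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dimred import Fingerprints, SVDResult
from .exceptions import ValidationError

__all__ = [
    "Lattice",
    "FLSOMConfig",
    "TrainedSOM",
    "init_lattice_linear",
    "best_matching_unit",
    "quantization_error",
    "batch_epoch",
    "adapt_learning",
    "train_flsom",
    "suggest_lattice_size",
]

# neurons whose Gaussian neighborhood collects less total mass than this
# keep their previous weights (prevents 0/0 in the batch update)
MIN_NEIGHBORHOOD_MASS = 1e-12


@dataclass
class Lattice:
    """rows x cols grid of k-dimensional neuron weight vectors."""

    rows: int
    cols: int
    weights: np.ndarray  # (rows, cols, k)
    k: int

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.rows * self.cols < 4:
            raise ValidationError("lattice needs at least 4 neurons")
        if self.weights.shape != (self.rows, self.cols, self.k):
            raise ValidationError(
                f"weight array shape {self.weights.shape} != ({self.rows}, {self.cols}, {self.k})"
            )
        if not np.all(np.isfinite(self.weights)):
            raise ValidationError("lattice weights must be finite")

    def flat_weights(self) -> np.ndarray:
        """(rows*cols, k) view in row-major neuron order."""
        return self.weights.reshape(-1, self.k)


@dataclass
class FLSOMConfig:
    """Training schedule parameters.

    sigma0
        Initial neighborhood radius in grid units; ``None`` means
        ``max(rows, cols) / 2``.
    sigma_min, alpha_min
        Floors for the radius and the learning factor.
    decay_fast, decay_slow
        Multiplicative radius decay applied in the productive and slow
        phases respectively (``decay_fast <= decay_slow``).
    improvement_target
        Relative QE improvement per epoch that counts as "productive".
    stop_epsilon
        |dQE| threshold that stops training.
    """

    sigma0: float | None = None
    sigma_min: float = 1.0
    alpha0: float = 1.0
    alpha_min: float = 0.05
    decay_fast: float = 0.90
    decay_slow: float = 0.98
    improvement_target: float = 0.01
    stop_epsilon: float = 1e-4
    max_epochs: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.sigma0 is not None and not (0 < self.sigma_min <= self.sigma0):
            raise ValidationError("need 0 < sigma_min <= sigma0")
        if not (0 < self.alpha_min <= self.alpha0 <= 1):
            raise ValidationError("need 0 < alpha_min <= alpha0 <= 1")
        if not (0 < self.decay_fast <= self.decay_slow < 1):
            raise ValidationError("need 0 < decay_fast <= decay_slow < 1")
        if not self.stop_epsilon > 0:
            raise ValidationError("stop_epsilon must be positive")
        if self.max_epochs < 1:
            raise ValidationError("max_epochs must be >= 1")

    def resolved_sigma0(self, rows: int, cols: int) -> float:
        if self.sigma0 is not None:
            return float(self.sigma0)
        return max(max(rows, cols) / 2.0, self.sigma_min)


@dataclass
class TrainedSOM:
    """Training outcome: final lattice, QE trace and per-pattern BMUs."""

    lattice: Lattice
    qe_trace: list
    bmu_of_pattern: np.ndarray  # (n_patterns, 2) int, (row, col)
    epochs_run: int
    stopped_by: str  # "delta_qe" | "max_epochs"
    fingerprints: Fingerprints = None


def init_lattice_linear(svd: SVDResult, rows: int, cols: int) -> Lattice:
    """Imprint the initial lattice from the top two singular directions.

    Neuron (r, c) gets weight ``a_r * sigma1 * e1 + b_c * sigma2 * e2`` in
    fingerprint coordinates, where e1, e2 are the first two fingerprint-space
    axes, and a_r, b_c run linearly over [-1, +1] across rows and columns.
    The grid is therefore a flat sheet spanning the two dominant directions
    of the data, centered on the (centered) data mean — the zero fingerprint.
    If k == 1 the second axis degenerates to zero.
    """
    if rows < 2 or cols < 2:
        raise ValidationError("lattice needs rows >= 2 and cols >= 2")
    k = svd.k
    s1 = float(svd.singular_values[0])
    s2 = float(svd.singular_values[1]) if k >= 2 else 0.0
    a = np.linspace(-1.0, 1.0, rows)
    b = np.linspace(-1.0, 1.0, cols)
    weights = np.zeros((rows, cols, k))
    weights[:, :, 0] = s1 * a[:, None]
    if k >= 2:
        weights[:, :, 1] = s2 * b[None, :]
    return Lattice(rows=rows, cols=cols, weights=weights, k=k)


def _bmu_indices(lattice: Lattice, X: np.ndarray) -> np.ndarray:
    """Row-major flat BMU index for each row of X; ties -> lowest index."""
    W = lattice.flat_weights()
    # squared distances via the expansion ||x||^2 - 2 x.w + ||w||^2
    d2 = (
        np.sum(X * X, axis=1)[:, None]
        - 2.0 * X @ W.T
        + np.sum(W * W, axis=1)[None, :]
    )
    return np.argmin(d2, axis=1)


def best_matching_unit(lattice: Lattice, x) -> tuple:
    """Grid coordinate of the neuron nearest to ``x`` (Euclidean).

    Ties are broken by the lowest row-major linear index.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (lattice.k,):
        raise ValidationError(f"vector has shape {x.shape}, lattice k={lattice.k}")
    flat = int(_bmu_indices(lattice, x[None, :])[0])
    return (flat // lattice.cols, flat % lattice.cols)


def quantization_error(lattice: Lattice, fingerprints: Fingerprints) -> float:
    """Mean Euclidean distance from each pattern to its BMU weight."""
    if fingerprints.n_patterns == 0:
        raise ValidationError("quantization error is undefined for zero patterns")
    if fingerprints.k != lattice.k:
        raise ValidationError(f"fingerprint k={fingerprints.k} != lattice k={lattice.k}")
    X = fingerprints.vectors
    W = lattice.flat_weights()
    flat = _bmu_indices(lattice, X)
    return float(np.mean(np.linalg.norm(X - W[flat], axis=1)))


def _grid_coords(rows: int, cols: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)


def batch_epoch(lattice: Lattice, fingerprints: Fingerprints, sigma: float, alpha: float) -> Lattice:
    """One batch update: blend each neuron toward its neighborhood-weighted mean.

    BMUs are computed once from the pre-update lattice.  With
    ``h(b, j) = exp(-grid_dist(b, j)^2 / (2 sigma^2))`` (Euclidean distance
    between grid coordinates), neuron j's target is the h-weighted mean of
    all patterns, and its new weight is ``(1 - alpha) w_j + alpha target_j``.
    Neurons with negligible total neighborhood mass keep their weights.
    """
    if not sigma > 0:
        raise ValidationError("sigma must be positive")
    if not (0 < alpha <= 1):
        raise ValidationError("alpha must lie in (0, 1]")
    if fingerprints.k != lattice.k:
        raise ValidationError(f"fingerprint k={fingerprints.k} != lattice k={lattice.k}")
    X = fingerprints.vectors
    n = X.shape[0]
    coords = _grid_coords(lattice.rows, lattice.cols)  # (m, 2)
    bmu = _bmu_indices(lattice, X)  # (n,)
    # pairwise squared grid distances between BMU cells and all neurons
    diff = coords[bmu][:, None, :] - coords[None, :, :]  # (n, m, 2)
    d2 = np.sum(diff * diff, axis=2)
    h = np.exp(-d2 / (2.0 * sigma * sigma))  # (n, m)
    mass = h.sum(axis=0)  # (m,)
    numer = h.T @ X  # (m, k)
    W = lattice.flat_weights().copy()
    ok = mass >= MIN_NEIGHBORHOOD_MASS
    target = np.where(ok[:, None], numer / np.where(ok, mass, 1.0)[:, None], W)
    W_new = (1.0 - alpha) * W + alpha * target
    W_new[~ok] = W[~ok]
    return Lattice(
        rows=lattice.rows,
        cols=lattice.cols,
        weights=W_new.reshape(lattice.rows, lattice.cols, lattice.k),
        k=lattice.k,
    )


def adapt_learning(
    qe_prev: float,
    qe_curr: float,
    sigma: float,
    alpha: float,
    config: FLSOMConfig,
) -> tuple:
    """Anneal the schedule from the QE change of the last epoch.

    Let ``dQE = qe_prev - qe_curr`` and ``r = dQE / qe_prev`` (0 when
    qe_prev == 0, +inf before the first epoch).  Three phases:

    * productive (r >= improvement_target): cool the neighborhood fast,
      keep the learning factor;
    * slow (0 <= r < improvement_target): cool slowly and damp alpha by 0.9;
    * worsening (r < 0): freeze the neighborhood and halve alpha.

    Returns ``(sigma', alpha', stop)`` where ``stop`` is true iff qe_prev is
    finite and ``|dQE| < stop_epsilon``.
    """
    delta = qe_prev - qe_curr
    if qe_prev == 0:
        r = 0.0
    elif math.isinf(qe_prev):
        r = math.inf
    else:
        r = delta / qe_prev
    if r >= config.improvement_target:
        sigma_new, alpha_new = max(sigma * config.decay_fast, config.sigma_min), alpha
    elif r >= 0:
        sigma_new = max(sigma * config.decay_slow, config.sigma_min)
        alpha_new = max(alpha * 0.9, config.alpha_min)
    else:
        sigma_new, alpha_new = sigma, max(alpha * 0.5, config.alpha_min)
    stop = math.isfinite(qe_prev) and abs(delta) < config.stop_epsilon
    return sigma_new, alpha_new, stop


def train_flsom(
    fingerprints: Fingerprints,
    rows: int,
    cols: int,
    svd: SVDResult,
    config: FLSOMConfig | None = None,
) -> TrainedSOM:
    """Train an FLSOM on the fingerprints and return the final map.

    The lattice is initialized linearly from the singular directions and
    recentered on the fingerprint mean (a no-op for centered data), then
    batch epochs run until |dQE| drops below ``config.stop_epsilon`` or
    ``config.max_epochs`` is reached.  The run is fully deterministic.
    """
    if config is None:
        config = FLSOMConfig()
    if fingerprints.k != svd.k:
        raise ValidationError(f"fingerprint k={fingerprints.k} != SVD k={svd.k}")
    if fingerprints.n_patterns == 0:
        raise ValidationError("cannot train on zero patterns")

    lattice = init_lattice_linear(svd, rows, cols)
    center = fingerprints.vectors.mean(axis=0)
    if np.any(center != 0):
        lattice = replace(lattice, weights=lattice.weights + center)

    sigma = config.resolved_sigma0(rows, cols)
    alpha = float(config.alpha0)
    qe_prev = math.inf
    qe_trace: list = []
    stopped_by = "max_epochs"
    for _ in range(config.max_epochs):
        lattice = batch_epoch(lattice, fingerprints, sigma, alpha)
        qe = quantization_error(lattice, fingerprints)
        qe_trace.append(qe)
        sigma, alpha, stop = adapt_learning(qe_prev, qe, sigma, alpha, config)
        qe_prev = qe
        if stop:
            stopped_by = "delta_qe"
            break

    flat = _bmu_indices(lattice, fingerprints.vectors)
    bmu = np.stack([flat // cols, flat % cols], axis=1).astype(int)
    return TrainedSOM(
        lattice=lattice,
        qe_trace=qe_trace,
        bmu_of_pattern=bmu,
        epochs_run=len(qe_trace),
        stopped_by=stopped_by,
        fingerprints=fingerprints,
    )


def suggest_lattice_size(n_patterns: int, svd: SVDResult) -> tuple:
    """Advisory emergent-map size: >= 5 neurons per pattern, aspect ratio
    following the ratio of the top two singular values (clipped to [1, 4])."""
    target = max(5 * n_patterns, 4)
    s1 = float(svd.singular_values[0])
    s2 = float(svd.singular_values[1]) if svd.k >= 2 else 0.0
    aspect = s1 / s2 if s2 > 0 else 4.0
    aspect = min(max(aspect, 1.0), 4.0)
    rows = max(2, math.ceil(math.sqrt(target * aspect)))
    cols = max(2, math.ceil(target / rows))
    return rows, cols
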