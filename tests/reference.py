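"""Independently coded brute-force references for oracle tests.

Every function here is written as a plain double/triple loop, independent of
the vectorized implementation paths it is used to check.
"""

import math

import numpy as np


def ref_bmu(weights, x):
    """Exhaustive scan; ties -> lowest row-major index."""
    rows, cols, _ = weights.shape
    best, best_d = None, math.inf
    for r in range(rows):
        for c in range(cols):
            d = math.dist(weights[r, c], x)
            if d < best_d:
                best, best_d = (r, c), d
    return best


def ref_quantization_error(weights, X):
    total = 0.0
    for x in X:
        r, c = ref_bmu(weights, x)
        total += math.dist(weights[r, c], x)
    return total / len(X)


def ref_batch_epoch(weights, X, sigma, alpha, min_mass=1e-12):
    """Double-loop batch update with Gaussian grid neighborhood."""
    rows, cols, k = weights.shape
    bmus = [ref_bmu(weights, x) for x in X]
    new = weights.copy()
    for r in range(rows):
        for c in range(cols):
            mass = 0.0
            num = np.zeros(k)
            for (br, bc), x in zip(bmus, X):
                d2 = (br - r) ** 2 + (bc - c) ** 2
                h = math.exp(-d2 / (2.0 * sigma * sigma))
                mass += h
                num += h * x
            if mass >= min_mass:
                target = num / mass
                new[r, c] = (1 - alpha) * weights[r, c] + alpha * target
    return new


def ref_umatrix(weights):
    """Per-neuron mean distance to existing 8-neighbors, by explicit loop."""
    rows, cols, _ = weights.shape
    heights = np.zeros((rows, cols))
    for r in range(rows):
        for c in range(cols):
            ds = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols:
                        ds.append(math.dist(weights[r, c], weights[rr, cc]))
            heights[r, c] = sum(ds) / len(ds)
    return heights


def _reflect(i, n):
    # scipy "reflect" boundary: (d c b a | a b c d | d c b a)
    while i < 0 or i >= n:
        i = -1 - i if i < 0 else 2 * n - 1 - i
    return i


def _ref_gradients(image, sigma, radius):
    """Blurred Sobel gradients of the dissimilarity field, by explicit loops."""
    field = 1.0 - np.asarray(image, dtype=float)
    rows, cols = field.shape

    kernel = [math.exp(-(i * i) / (2 * sigma * sigma)) for i in range(-radius, radius + 1)]
    s = sum(kernel)
    kernel = [k / s for k in kernel]

    def blur1d(a, axis):
        out = np.zeros_like(a)
        for r in range(rows):
            for c in range(cols):
                acc = 0.0
                for t in range(-radius, radius + 1):
                    if axis == 0:
                        acc += kernel[t + radius] * a[_reflect(r + t, rows), c]
                    else:
                        acc += kernel[t + radius] * a[r, _reflect(c + t, cols)]
                out[r, c] = acc
        return out

    sm = blur1d(blur1d(field, 0), 1)

    # Sobel: correlate with [-1, 0, 1] along the derivative axis and
    # [1, 2, 1] along the other, reflect boundaries
    gy = np.zeros_like(sm)
    for r in range(rows):
        for c in range(cols):
            for dr, wd in ((-1, -1.0), (1, 1.0)):
                for dc, ws in ((-1, 1.0), (0, 2.0), (1, 1.0)):
                    gy[r, c] += wd * ws * sm[_reflect(r + dr, rows), _reflect(c + dc, cols)]
    gx = np.zeros_like(sm)
    for r in range(rows):
        for c in range(cols):
            for dc, wd in ((-1, -1.0), (1, 1.0)):
                for dr, ws in ((-1, 1.0), (0, 2.0), (1, 1.0)):
                    gx[r, c] += wd * ws * sm[_reflect(r + dr, rows), _reflect(c + dc, cols)]
    return gx, gy


def ref_gradient_magnitude(image, sigma, radius):
    gx, gy = _ref_gradients(image, sigma, radius)
    return np.hypot(gx, gy)


def ref_canny(image, sigma, radius, low, high):
    """Loop-based Canny on the dissimilarity field 1 - image."""
    rows, cols = np.asarray(image).shape
    gx, gy = _ref_gradients(image, sigma, radius)
    mag = np.hypot(gx, gy)
    mag_max = mag.max()
    if mag_max == 0:
        return np.zeros((rows, cols), dtype=bool)

    nms = np.zeros_like(mag)
    for r in range(rows):
        for c in range(cols):
            angle = math.degrees(math.atan2(gy[r, c], gx[r, c])) % 180.0
            if angle < 22.5 or angle >= 157.5:
                dr, dc = 0, 1
            elif angle < 67.5:
                dr, dc = 1, 1
            elif angle < 112.5:
                dr, dc = 1, 0
            else:
                dr, dc = 1, -1

            def at(rr, cc):
                return mag[rr, cc] if 0 <= rr < rows and 0 <= cc < cols else 0.0

            # strict on the positive-direction neighbor thins plateau ties
            if mag[r, c] > at(r + dr, c + dc) and mag[r, c] >= at(r - dr, c - dc):
                nms[r, c] = mag[r, c]

    strong = [(r, c) for r in range(rows) for c in range(cols) if nms[r, c] >= high * mag_max]
    weak = nms >= low * mag_max
    mask = np.zeros((rows, cols), dtype=bool)
    stack = list(strong)
    while stack:
        r, c = stack.pop()
        if mask[r, c]:
            continue
        mask[r, c] = True
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols and weak[rr, cc] and not mask[rr, cc]:
                    stack.append((rr, cc))
    return mask


def ref_region_growing(mask, min_region_size=2):
    """BFS flood fill of 4-connected non-edge pixels, row-major seeds."""
    rows, cols = mask.shape
    labels = np.zeros((rows, cols), dtype=int)
    comps = []
    for r0 in range(rows):
        for c0 in range(cols):
            if mask[r0, c0] or labels[r0, c0] != 0:
                continue
            comp = []
            queue = [(r0, c0)]
            labels[r0, c0] = -1  # visited marker
            while queue:
                r, c = queue.pop(0)
                comp.append((r, c))
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols and not mask[rr, cc] and labels[rr, cc] == 0:
                        labels[rr, cc] = -1
                        queue.append((rr, cc))
            comps.append(comp)
    labels[:] = 0
    lab = 0
    for comp in comps:
        if len(comp) >= min_region_size:
            lab += 1
            for r, c in comp:
                labels[r, c] = lab
    return labels, lab


def ref_singular_values(A, k):
    """Singular values from the eigen-decomposition of the Gram matrix."""
    G = A.T @ A
    eig = np.linalg.eigvalsh(G)[::-1]
    return np.sqrt(np.clip(eig, 0.0, None))[:k]
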