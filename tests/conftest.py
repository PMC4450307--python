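"""Shared fixtures and independent reference implementations (oracles).

The oracles here are deliberately written from scratch, sharing no code
with the package: a BFS flood-fill labeler, a dense tridiagonal solve of
the natural-spline second-derivative system, and a literal straight-line
trace of the fuzzy ART resonance flow.  Tests compare the production code
against them.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from appendix_us.imgio import BinaryImage, GrayscaleImage

# ---------------------------------------------------------------------------
# flood-fill labeling oracle


def flood_fill_label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """BFS connected-component labeling; labels in raster order of each
    component's first pixel."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    labels = np.zeros((h, w), dtype=np.int32)
    next_label = 0
    for y in range(h):
        for x in range(w):
            if mask[y, x] and labels[y, x] == 0:
                next_label += 1
                labels[y, x] = next_label
                queue = deque([(y, x)])
                while queue:
                    cy, cx = queue.popleft()
                    for dy, dx in nbrs:
                        ny, nx = cy + dy, cx + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and labels[ny, nx] == 0:
                            labels[ny, nx] = next_label
                            queue.append((ny, nx))
    return labels


# ---------------------------------------------------------------------------
# natural cubic spline oracle: solve for second derivatives M_i directly


def natural_spline_eval(xs, ys, xq):
    """Evaluate the natural cubic spline through (xs, ys) at xq by solving
    the classic tridiagonal system for the knot second derivatives."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    n = xs.size
    h = np.diff(xs)
    m = np.zeros(n)
    if n > 2:
        a = np.zeros((n - 2, n - 2))
        rhs = np.zeros(n - 2)
        for i in range(1, n - 1):
            r = i - 1
            if r > 0:
                a[r, r - 1] = h[i - 1]
            a[r, r] = 2.0 * (h[i - 1] + h[i])
            if r < n - 3:
                a[r, r + 1] = h[i]
            rhs[r] = 6.0 * ((ys[i + 1] - ys[i]) / h[i] - (ys[i] - ys[i - 1]) / h[i - 1])
        m[1:-1] = np.linalg.solve(a, rhs)
    xq = np.atleast_1d(np.asarray(xq, dtype=float))
    out = np.empty_like(xq)
    for k, x in enumerate(xq):
        i = int(np.clip(np.searchsorted(xs, x, side="right") - 1, 0, n - 2))
        hi = h[i]
        t1, t0 = xs[i + 1] - x, x - xs[i]
        out[k] = (
            m[i] * t1**3 / (6 * hi)
            + m[i + 1] * t0**3 / (6 * hi)
            + (ys[i] - m[i] * hi**2 / 6) * t1 / hi
            + (ys[i + 1] - m[i + 1] * hi**2 / 6) * t0 / hi
        )
    return out if out.size > 1 else float(out[0])


# ---------------------------------------------------------------------------
# fuzzy ART straight-line trace oracle


def fuzzyart_trace(values, rho, alpha, beta_max=1.0, max_clusters=16):
    """Literal trace of the resonance flow, one pixel at a time.

    Returns (labels, weights, trajectories) where trajectories[j] is the
    sequence of values weight j has taken (for monotonicity checks).
    """
    weights: list[float] = []
    trajectories: list[list[float]] = []
    labels = []
    for x in values:
        x = float(x)
        if not weights:
            weights.append(x)
            trajectories.append([x])
            labels.append(0)
            continue
        candidates = list(range(len(weights)))
        assigned = None
        while candidates:
            # winner: maximum of 1 - O_j (= minimum distance), lowest index on ties
            best = candidates[0]
            best_v = 1.0 - abs(weights[best] - x) / beta_max
            for j in candidates[1:]:
                v = 1.0 - abs(weights[j] - x) / beta_max
                if v > best_v:
                    best, best_v = j, v
            w = weights[best]
            if w == x or min(w, x) / beta_max > rho:
                weights[best] = alpha * min(x, w) + (1.0 - alpha) * w
                trajectories[best].append(weights[best])
                assigned = best
                break
            candidates.remove(best)
        if assigned is None:
            if len(weights) < max_clusters:
                weights.append(x)
                trajectories.append([x])
                assigned = len(weights) - 1
            else:
                best = 0
                best_d = abs(weights[0] - x)
                for j in range(1, len(weights)):
                    d = abs(weights[j] - x)
                    if d < best_d:
                        best, best_d = j, d
                assigned = best
        labels.append(assigned)
    return labels, weights, trajectories


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture()
def gradient_image() -> GrayscaleImage:
    """64x64 raster covering many brightness values."""
    rng = np.random.default_rng(42)
    return GrayscaleImage(rng.integers(0, 256, size=(64, 64)).astype(np.uint8))


def make_band_mask(height=60, width=100, rows=(10, 13), gap=None) -> BinaryImage:
    """Horizontal foreground band over [rows[0], rows[1]) with an optional
    column gap [gap[0], gap[1])."""
    m = np.zeros((height, width), dtype=np.uint8)
    m[rows[0] : rows[1], :] = 1
    if gap is not None:
        m[:, gap[0] : gap[1]] = 0
    return BinaryImage(m)
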