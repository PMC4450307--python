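"""Distance-based fuzzy ART clustering of pixel brightness.

Fuzzy ART is an unsupervised, incremental resonance network.  Here each
input is a single normalized brightness x = P/255 in [0, 1] and each
committed cluster j keeps a scalar prototype weight w_j in [0, 1]:

* node output (error):      O_j = |w_j - x| / beta_max
* winner:                   the cluster with minimum O_j (ties -> lowest index)
* vigilance (resonance):    w_j == x, or min(w_j, x) / beta_max > rho
* learning:                 w' = alpha * min(x, w) + (1 - alpha) * w

A pixel resonates with the nearest cluster that passes vigilance and pulls
its prototype toward the fuzzy minimum; if no cluster resonates a new one
is committed at the pixel's value, up to ``max_clusters`` (beyond the cap
the pixel is assigned to the nearest prototype without learning).  The
pass is a single deterministic row-major sweep: same pixels, same
parameters -> bit-identical clusters.

The exact-match clause is part of this package's vigilance dialect: an
input identical to a prototype is maximally similar and always resonates
(leaving the weight unchanged), whatever the vigilance level.  Without it
the min-based test alone would let a run of identical dark pixels found
duplicate clusters until the cap is exhausted, since a pixel with
x <= rho * beta_max can never satisfy min(w, x)/beta_max > rho.  Dark
pixels that match no prototype exactly still always found new clusters
while capacity remains, which keeps the cluster budget filled from the
earliest distinct brightnesses and then lets the network behave as a
nearest-prototype quantizer — stable and entirely order-determined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NoClustersError, NoPixelsError
from .fascia import RoiMask
from .imgio import GrayscaleImage

#: Label used for pixels outside the region of interest.
NON_ROI = -1


@dataclass(frozen=True)
class FuzzyARTParams:
    """Vigilance rho in (0,1], learning rate alpha in [0,1], brightness
    normalizer beta_max > 0, and the cluster-count cap."""

    rho: float = 0.85
    alpha: float = 0.5
    beta_max: float = 1.0
    max_clusters: int = 16

    def __post_init__(self) -> None:
        if not (0 < self.rho <= 1):
            raise ValueError(f"rho must be in (0, 1], got {self.rho}")
        if not (0 <= self.alpha <= 1):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not self.beta_max > 0:
            raise ValueError(f"beta_max must be > 0, got {self.beta_max}")
        if self.max_clusters < 1:
            raise ValueError(f"max_clusters must be >= 1, got {self.max_clusters}")


@dataclass
class FuzzyARTState:
    """Committed prototypes and per-cluster pixel counts after a pass."""

    weights: list[float] = field(default_factory=list)
    counts: list[int] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.weights)


@dataclass
class ClusterAssignment:
    """Per-pixel cluster indices over an ROI raster (``NON_ROI`` outside)
    plus final prototypes rescaled to [0, 255]."""

    labels: np.ndarray
    prototypes: np.ndarray

    @property
    def n_clusters(self) -> int:
        return int(self.prototypes.size)


def normalize_brightness(img: GrayscaleImage) -> np.ndarray:
    """Brightness / 255 as float64 in [0, 1]."""
    return img.pixels.astype(np.float64) / 255.0


def node_output(w: float, x: float, beta_max: float = 1.0) -> float:
    """Distance score O_j = |w - x| / beta_max (scalar Euclidean distance)."""
    return abs(w - x) / beta_max


def select_winner(outputs) -> int:
    """Index of the minimum distance score; ties break to the lowest index."""
    outputs = list(outputs)
    if not outputs:
        raise NoClustersError("no committed clusters; caller must commit the first")
    return min(range(len(outputs)), key=outputs.__getitem__)


def vigilance_test(w: float, x: float, params: FuzzyARTParams) -> bool:
    """Resonance check: exact match always resonates, otherwise
    min(w, x) / beta_max > rho."""
    return w == x or min(w, x) / params.beta_max > params.rho


def update_weight(w: float, x: float, alpha: float) -> float:
    """Fuzzy ART learning: w' = alpha * min(x, w) + (1 - alpha) * w."""
    return alpha * min(x, w) + (1.0 - alpha) * w


def round_half_up(values: np.ndarray) -> np.ndarray:
    """Round-half-up to integer (0.5 -> 1), the prototype rounding rule."""
    return np.floor(np.asarray(values, dtype=np.float64) * 1.0 + 0.5).astype(np.int64)


def cluster_pixels(values, params: FuzzyARTParams) -> tuple[np.ndarray, FuzzyARTState]:
    """Single-pass fuzzy ART over a sequence of normalized brightnesses.

    The first pixel commits cluster 0 at its own value.  Each subsequent
    pixel tries the committed clusters nearest-first and resonates with the
    first one passing vigilance; otherwise it commits a new cluster (below
    the cap) or is assigned to the nearest prototype without learning.

    Returns (labels, state) with ``labels[i]`` the cluster of ``values[i]``.
    """
    vals = np.asarray(values, dtype=np.float64).ravel()
    if vals.size == 0:
        raise NoPixelsError("cannot cluster an empty pixel sequence")
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("normalized brightness must lie in [0, 1]")
    rho, alpha, bmax = params.rho, params.alpha, params.beta_max
    cap = params.max_clusters
    weights: list[float] = []
    counts: list[int] = []
    labels = np.empty(vals.size, dtype=np.int32)
    vigilance_floor = rho * bmax  # x <= this can never resonate
    for i, x in enumerate(vals.tolist()):
        if not weights:
            weights.append(x)
            counts.append(1)
            labels[i] = 0
            continue
        assigned = -1
        if x > vigilance_floor:
            # resonance search, nearest cluster first (stable sort: ties
            # fall to the lower index); exact matches have distance 0 and
            # are visited first, so the equality clause is subsumed here
            dists = [abs(w - x) for w in weights]
            for j in sorted(range(len(dists)), key=dists.__getitem__):
                if weights[j] == x or min(weights[j], x) > vigilance_floor:
                    weights[j] = alpha * min(x, weights[j]) + (1.0 - alpha) * weights[j]
                    assigned = j
                    break
        else:
            # below the vigilance floor only an exact match can resonate;
            # the nearest cluster (lowest index on ties) is the candidate
            best, bestd = 0, abs(weights[0] - x)
            for j in range(1, len(weights)):
                d = abs(weights[j] - x)
                if d < bestd:
                    best, bestd = j, d
            if bestd == 0.0:  # w == x: exact-match resonance
                w = weights[best]
                weights[best] = alpha * min(x, w) + (1.0 - alpha) * w
                assigned = best
        if assigned < 0:
            if len(weights) < cap:
                weights.append(x)
                counts.append(0)
                assigned = len(weights) - 1
            else:
                best, bestd = 0, abs(weights[0] - x)
                for j in range(1, len(weights)):
                    d = abs(weights[j] - x)
                    if d < bestd:
                        best, bestd = j, d
                assigned = best
        counts[assigned] += 1
        labels[i] = assigned
    return labels, FuzzyARTState(weights=weights, counts=counts)


def cluster_roi(
    img: GrayscaleImage, roi: RoiMask, params: FuzzyARTParams
) -> tuple[ClusterAssignment, FuzzyARTState]:
    """Cluster the ROI pixels of an image in row-major order.

    Non-ROI pixels carry the ``NON_ROI`` sentinel in the label raster;
    prototypes are the final weights rescaled to [0, 255] (round-half-up).
    """
    sel = roi.mask.as_bool()
    if img.shape != sel.shape:
        raise ValueError(f"image {img.shape} and ROI {sel.shape} shapes differ")
    vals = normalize_brightness(img)[sel]  # row-major by numpy indexing
    labels_1d, state = cluster_pixels(vals, params)
    raster = np.full(img.shape, NON_ROI, dtype=np.int32)
    raster[sel] = labels_1d
    prototypes = round_half_up(np.asarray(state.weights) * 255.0).astype(np.uint8)
    return ClusterAssignment(labels=raster, prototypes=prototypes), state


def quantize(img: GrayscaleImage, roi: RoiMask, assign: ClusterAssignment) -> GrayscaleImage:
    """Replace each ROI pixel by its cluster's prototype brightness;
    everything outside the ROI becomes 0."""
    sel = roi.mask.as_bool()
    out = np.zeros(img.shape, dtype=np.uint8)
    if assign.n_clusters:
        out[sel] = assign.prototypes[assign.labels[sel]]
    return GrayscaleImage(out, pixel_spacing=img.pixel_spacing)
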