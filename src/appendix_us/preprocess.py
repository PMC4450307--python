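"""Contrast enhancement and noise removal.

Three steps prepare an abdominal ultrasound frame for fascia detection:

1. *Ends-in search stretching* — a linear contrast stretch that clips a
   small fraction of both histogram tails to thresholds ``Min``/``Max`` and
   maps the remaining range onto [0, 255]:

   ``S = 0`` for ``P <= Min``; ``S = 255`` for ``P >= Max``;
   ``S = floor(255 * (P - Min) / (Max - Min))`` otherwise.

2. *Max-Min binarization* — threshold at the midpoint of the observed
   minimum and maximum brightness of the stretched image; a pixel is
   foreground iff strictly above the midpoint.

3. *Region labeling with a size filter* — connected components of the
   binary image are labeled and components smaller than ``min_area``
   pixels (default 1500) are discarded as speckle noise, leaving the
   fascia-scale structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .errors import DegenerateContrastError
from .imgio import BinaryImage, GrayscaleImage

#: Default clipped tail fraction on each side of the histogram.
DEFAULT_TAIL_FRAC = 0.01
#: Default minimum component area (pixels) kept by the noise filter.
DEFAULT_MIN_AREA = 1500
#: Default pixel connectivity for component labeling.
DEFAULT_CONNECTIVITY = 8


@dataclass(frozen=True)
class StretchBounds:
    """Thresholds ``Min``/``Max`` of the ends-in stretch, 0 <= min_t < max_t <= 255."""

    min_t: int
    max_t: int

    def __post_init__(self) -> None:
        if not (0 <= self.min_t < self.max_t <= 255):
            raise ValueError(
                f"require 0 <= min_t < max_t <= 255, got ({self.min_t}, {self.max_t})"
            )


@dataclass(frozen=True)
class RegionStats:
    """Per-component statistics of a labeled mask.

    ``bbox`` is (min_x, min_y, max_x, max_y), inclusive; ``centroid`` is
    (x, y) in pixel coordinates.
    """

    label: int
    area: int
    bbox: tuple[int, int, int, int]
    centroid: tuple[float, float]

    @property
    def bbox_width(self) -> int:
        return self.bbox[2] - self.bbox[0] + 1

    @property
    def bbox_height(self) -> int:
        return self.bbox[3] - self.bbox[1] + 1


@dataclass
class LabeledRegions:
    """Integer label raster (0 = background, components 1..K) plus per-label stats."""

    labels: np.ndarray
    regions: list[RegionStats]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)


def compute_stretch_bounds(
    img: GrayscaleImage,
    low_frac: float = DEFAULT_TAIL_FRAC,
    high_frac: float = DEFAULT_TAIL_FRAC,
) -> StretchBounds:
    """Choose ``Min``/``Max`` from the cumulative brightness histogram.

    ``min_t`` is the smallest occupied brightness ``b`` whose cumulative
    fraction of pixels ``<= b`` reaches ``low_frac``; ``max_t`` the largest
    occupied ``b`` whose tail fraction ``>= b`` reaches ``high_frac``.  With
    zero fractions this returns the true extremes.  Should the rule collapse
    (``min_t >= max_t``), the bounds widen to the image's true min/max.
    """
    if not (0 <= low_frac < 0.5 and 0 <= high_frac < 0.5):
        raise ValueError("tail fractions must lie in [0, 0.5)")
    if low_frac + high_frac >= 1:
        raise ValueError("low_frac + high_frac must be < 1")
    hist = np.bincount(img.pixels.ravel(), minlength=256).astype(np.float64)
    n = hist.sum()
    occupied = np.flatnonzero(hist)
    if occupied.size < 2:
        raise DegenerateContrastError(
            "image has a single brightness value; contrast stretch is undefined"
        )
    cum_le = np.cumsum(hist) / n  # fraction of pixels <= b
    tail_ge = 1.0 - np.concatenate(([0.0], cum_le[:-1]))  # fraction >= b
    min_candidates = np.flatnonzero((cum_le >= low_frac) & (cum_le > 0))
    max_candidates = np.flatnonzero((tail_ge >= high_frac) & (tail_ge > 0))
    min_t = int(min_candidates[0])
    max_t = int(max_candidates[-1])
    if min_t >= max_t:
        min_t, max_t = int(occupied[0]), int(occupied[-1])
    return StretchBounds(min_t, max_t)


def ends_in_stretch(img: GrayscaleImage, bounds: StretchBounds) -> GrayscaleImage:
    """Apply the ends-in linear stretch with floor rounding.

    Monotone in brightness; pixels at or below ``min_t`` map to 0, at or
    above ``max_t`` to 255.
    """
    p = img.pixels.astype(np.int64)
    span = bounds.max_t - bounds.min_t
    mid = (255 * (p - bounds.min_t)) // span  # floor for non-negative numerators
    out = np.where(p <= bounds.min_t, 0, np.where(p >= bounds.max_t, 255, mid))
    return GrayscaleImage(out.astype(np.uint8), pixel_spacing=img.pixel_spacing)


def max_min_binarize(img: GrayscaleImage) -> BinaryImage:
    """Threshold at the midpoint of the observed extremes.

    ``T = (min + max) / 2``; foreground iff brightness ``> T``.  A constant
    image yields an all-zero mask (nothing exceeds its own midpoint).
    """
    p = img.pixels
    t = (int(p.min()) + int(p.max())) / 2.0
    return BinaryImage((p > t).astype(np.uint8))


def _skimage_connectivity(connectivity: int) -> int:
    if connectivity == 4:
        return 1
    if connectivity == 8:
        return 2
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def label_regions(mask: BinaryImage, connectivity: int = DEFAULT_CONNECTIVITY) -> LabeledRegions:
    """Label maximal connected components of the foreground.

    Labels are assigned 1..K in raster-scan order of each component's first
    pixel, which makes the labeling deterministic and comparable across
    implementations.
    """
    conn = _skimage_connectivity(connectivity)
    raw = measure.label(mask.as_bool(), connectivity=conn)
    k = int(raw.max())
    if k == 0:
        return LabeledRegions(np.zeros(mask.shape, dtype=np.int32), [])
    # Relabel by raster order of each component's first pixel.
    flat = raw.ravel()
    first_idx = np.full(k + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed so that the earliest index wins
    first_idx[flat[nz[::-1]]] = nz[::-1]
    order = np.argsort(first_idx[1:], kind="stable")  # old labels, 0-based
    remap = np.zeros(k + 1, dtype=np.int32)
    remap[order + 1] = np.arange(1, k + 1)
    labels = remap[raw]
    regions = []
    for props in sorted(measure.regionprops(labels), key=lambda r: r.label):
        min_row, min_col, max_row, max_col = props.bbox
        cy, cx = props.centroid
        regions.append(
            RegionStats(
                label=int(props.label),
                area=int(props.area),
                bbox=(int(min_col), int(min_row), int(max_col) - 1, int(max_row) - 1),
                centroid=(float(cx), float(cy)),
            )
        )
    return LabeledRegions(labels, regions)


def remove_small_regions(lr: LabeledRegions, min_area: int = DEFAULT_MIN_AREA) -> BinaryImage:
    """Keep exactly the pixels of components with area >= ``min_area``."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    keep = [r.label for r in lr.regions if r.area >= min_area]
    if not keep:
        return BinaryImage(np.zeros(lr.labels.shape, dtype=np.uint8))
    keep_lut = np.zeros(int(lr.labels.max()) + 1, dtype=np.uint8)
    keep_lut[keep] = 1
    return BinaryImage(keep_lut[lr.labels])
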