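"""Bottom fascia-line reconstruction and the sub-fascia region of interest.

On abdominal ultrasound the fascia appears as bright near-horizontal bands;
the appendix lies in the organ area below the *bottom* band.  Acoustic
shadowing often breaks that band into disconnected segments, so the lowest
boundary of the detected fascia components is bridged with a natural cubic
spline — a piecewise cubic interpolant S_i on [x_i, x_{i+1}] with

* interpolation: S_i(x_i) = y_i, S_i(x_{i+1}) = y_{i+1},
* C1/C2 continuity at interior knots,
* natural boundary: S'' = 0 at both end knots,

and the region of interest is everything below the reconstructed curve
(plus a small safety margin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import FasciaNotFoundError
from .imgio import BinaryImage, GrayscaleImage
from .preprocess import DEFAULT_CONNECTIVITY, LabeledRegions, label_regions

#: A component counts as fascia when its bbox width is at least this
#: fraction of the image width.
DEFAULT_WIDTH_FRAC = 0.15
#: Components whose bbox bottom lies within this fraction of the image
#: height from the lowest fascia component belong to the bottom line.
DEFAULT_BOTTOM_TOL_FRAC = 0.15
#: Boundary points are thinned to every k-th column before spline fitting.
DEFAULT_KNOT_STRIDE = 8
#: ROI starts this many rows below the reconstructed curve.
DEFAULT_ROI_MARGIN = 2


@dataclass
class BoundaryPoints:
    """Ordered (x, y) pixel coordinates with strictly increasing x."""

    xs: np.ndarray
    ys: np.ndarray

    def __post_init__(self) -> None:
        self.xs = np.asarray(self.xs, dtype=np.int64)
        self.ys = np.asarray(self.ys, dtype=np.int64)
        if self.xs.shape != self.ys.shape or self.xs.ndim != 1:
            raise ValueError("xs and ys must be 1-D and of equal length")
        if self.xs.size and np.any(np.diff(self.xs) <= 0):
            raise ValueError("x coordinates must be strictly increasing")

    def __len__(self) -> int:
        return int(self.xs.size)

    def thin(self, stride: int = DEFAULT_KNOT_STRIDE) -> "BoundaryPoints":
        """Subsample every ``stride``-th point, always keeping the last one,
        so the spline spans the full x-extent without tracking per-column
        speckle jitter."""
        if stride < 1:
            raise ValueError("stride must be >= 1")
        if len(self) <= 2:
            return self
        idx = list(range(0, len(self) - 1, stride))
        idx.append(len(self) - 1)
        return BoundaryPoints(self.xs[idx], self.ys[idx])


@dataclass
class SplineCurve:
    """Natural cubic spline over ordered knots.

    ``coefficients`` has shape (4, n_intervals): row k holds the
    coefficient of ``(x - x_i)**(3 - k)`` on interval i.
    """

    knots: BoundaryPoints
    _spline: CubicSpline

    @property
    def coefficients(self) -> np.ndarray:
        return self._spline.c

    @property
    def x_min(self) -> float:
        return float(self.knots.xs[0])

    @property
    def x_max(self) -> float:
        return float(self.knots.xs[-1])

    def __call__(self, x, clamp: bool = False):
        """Evaluate y(x).  With ``clamp=True`` x is clipped to the knot
        span first, giving constant (zero-slope) extrapolation at the end
        knots instead of the cubic's natural runaway."""
        x = np.asarray(x, dtype=np.float64)
        if clamp:
            x = np.clip(x, self.x_min, self.x_max)
        return self._spline(x)

    def derivative(self, x, order: int = 1):
        return self._spline(np.asarray(x, dtype=np.float64), nu=order)


@dataclass
class RoiMask:
    """Binary mask of the organ area strictly below the bottom fascia curve."""

    mask: BinaryImage


def extract_bottom_boundary(
    mask: BinaryImage,
    width_frac: float = DEFAULT_WIDTH_FRAC,
    bottom_tol_frac: float = DEFAULT_BOTTOM_TOL_FRAC,
    connectivity: int = DEFAULT_CONNECTIVITY,
    labeled: LabeledRegions | None = None,
) -> BoundaryPoints:
    """Per-column lowest pixel of the bottom fascia line.

    Fascia components are those whose bounding-box width is at least
    ``width_frac`` of the image width; among them only components whose
    bbox bottom lies within ``bottom_tol_frac`` of the image height from
    the lowest one contribute (an upper fascia band must not fill in the
    bottom band's gaps).  Columns with no bottom-fascia pixel are omitted:
    they are exactly the gaps the spline will bridge.
    """
    lr = labeled if labeled is not None else label_regions(mask, connectivity)
    min_width = width_frac * mask.width
    fascia = [r for r in lr.regions if r.bbox_width >= min_width]
    if not fascia:
        raise FasciaNotFoundError(
            f"no component with bbox width >= {min_width:.0f} px qualifies as fascia"
        )
    max_bottom = max(r.bbox[3] for r in fascia)
    tol = bottom_tol_frac * mask.height
    bottom_labels = [r.label for r in fascia if r.bbox[3] >= max_bottom - tol]
    lut = np.zeros(int(lr.labels.max()) + 1, dtype=bool)
    lut[bottom_labels] = True
    sel = lut[lr.labels]  # pixels of bottom-line components
    cols = np.flatnonzero(sel.any(axis=0))
    rows = np.arange(mask.height)[:, None]
    lowest = np.where(sel, rows, -1).max(axis=0)
    return BoundaryPoints(cols, lowest[cols])


def fit_natural_spline(pts: BoundaryPoints) -> SplineCurve:
    """Fit a natural cubic spline through the boundary knots."""
    if len(pts) < 2:
        raise ValueError("need at least 2 knots to fit a spline")
    cs = CubicSpline(
        pts.xs.astype(np.float64), pts.ys.astype(np.float64), bc_type="natural"
    )
    return SplineCurve(pts, cs)


def bridge_gaps(mask: BinaryImage, curve: SplineCurve) -> BinaryImage:
    """Rasterize the spline across its span into the mask, reconnecting
    the fascia segments; never removes pixels.  Curve ordinates falling
    outside the raster are clipped to the image."""
    out = mask.mask.copy()
    xs = np.arange(int(np.ceil(curve.x_min)), int(np.floor(curve.x_max)) + 1)
    if xs.size:
        ys = np.clip(np.rint(curve(xs)).astype(np.int64), 0, mask.height - 1)
        out[ys, xs] = 1
    return BinaryImage(out)


def roi_below_curve(
    img: GrayscaleImage, curve: SplineCurve, margin: int = DEFAULT_ROI_MARGIN
) -> RoiMask:
    """Mask of pixels strictly below the fascia curve plus ``margin`` rows.

    Outside the knot span the curve is extended horizontally at the end-knot
    height (zero slope), so the ROI reaches the image edges.
    """
    xs = np.arange(img.width)
    ycurve = curve(xs, clamp=True)
    rows = np.arange(img.height)[:, None]
    mask = (rows > ycurve[None, :] + margin).astype(np.uint8)
    return RoiMask(BinaryImage(mask))
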