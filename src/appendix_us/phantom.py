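"""Seeded synthetic ultrasound phantoms with exact ground truth.

No public dataset of appendix ultrasound exists, so every stage of the
pipeline is exercised on generated phantoms that emulate the relevant
scene content: a speckle-textured mid-gray background, bright horizontal
fascia bands (the bottom one broken by an acoustic-shadow gap), a dark
elliptical appendix below the bottom band, and optionally a dark
*irregular* ascites blob that acts as the false-positive distractor.

Speckle is modelled as multiplicative log-normal noise applied to the
whole composited scene.  Real ultrasound speckle is Rayleigh-family and
spatially correlated; the log-normal stand-in reproduces the salt-like
brightness granularity that the size filter and erosion stages must
defeat, which is what these phantoms are for.  Ground-truth masks are
exact by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from skimage import draw as skdraw

from .errors import DimensionError, PhantomSpecError
from .imgio import BinaryImage, GrayscaleImage

#: Default battery size and speckle scale.
DEFAULT_BATTERY_SIZE = 50
DEFAULT_SPECKLE_SIGMA = 0.15


@dataclass(frozen=True)
class FasciaBand:
    """Bright horizontal band: center row, thickness (rows), brightness."""

    y_center: int
    thickness: int
    brightness: int


@dataclass(frozen=True)
class AppendixBlob:
    """Dark rotated ellipse: center, semi-axes (px), angle (deg,
    counterclockwise from the +x axis), brightness."""

    center_x: float
    center_y: float
    semi_major: float
    semi_minor: float
    angle_deg: float
    brightness: int


@dataclass(frozen=True)
class AscitesBlob:
    """Dark irregular blob: a radial polygon whose vertex radii are
    jittered by ``roughness`` (fractional), guaranteeing low ellipticity."""

    center_x: float
    center_y: float
    mean_radius: float
    roughness: float
    brightness: int
    n_vertices: int = 24


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom; the seed fixes the image bit-exactly."""

    width: int = 512
    height: int = 420
    background: int = 110
    fascia_rows: tuple[FasciaBand, ...] = (
        FasciaBand(y_center=84, thickness=10, brightness=200),
        FasciaBand(y_center=160, thickness=12, brightness=200),
    )
    gap: tuple[int, int] = (220, 40)  # (x_start, x_width) of the bottom band's gap
    appendix: AppendixBlob | None = AppendixBlob(
        center_x=256, center_y=290, semi_major=55, semi_minor=24,
        angle_deg=15, brightness=30,
    )
    ascites: AscitesBlob | None = None
    speckle_sigma: float = DEFAULT_SPECKLE_SIGMA
    contrast: float = 1.0
    seed: int = 0


@dataclass
class PhantomTruth:
    """Exact ground-truth masks for the composited structures."""

    appendix_mask: BinaryImage
    fascia_mask: BinaryImage
    ascites_mask: BinaryImage


def _validate(spec: PhantomSpec) -> None:
    if spec.width < 1 or spec.height < 1:
        raise PhantomSpecError("phantom dimensions must be positive")
    if not spec.fascia_rows:
        raise PhantomSpecError("at least one fascia band is required")
    bottom = spec.fascia_rows[-1]
    for band in spec.fascia_rows:
        if band.brightness <= spec.background:
            raise PhantomSpecError("fascia brightness must exceed the background mean")
    if spec.appendix is not None:
        if spec.appendix.center_y <= bottom.y_center + bottom.thickness:
            raise PhantomSpecError("appendix center must lie below the bottom fascia band")
        if spec.appendix.brightness >= spec.background:
            raise PhantomSpecError("appendix brightness must be below the background mean")
    if not (0 <= spec.speckle_sigma):
        raise PhantomSpecError("speckle_sigma must be >= 0")
    if not (0 < spec.contrast <= 1):
        raise PhantomSpecError("contrast must lie in (0, 1]")


def _ellipse_mask(shape: tuple[int, int], blob: AppendixBlob) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - blob.center_x
    dy = yy - blob.center_y
    t = np.deg2rad(blob.angle_deg)
    u = dx * np.cos(t) + dy * np.sin(t)
    v = -dx * np.sin(t) + dy * np.cos(t)
    return (u / blob.semi_major) ** 2 + (v / blob.semi_minor) ** 2 <= 1.0


def _ascites_mask(
    shape: tuple[int, int], blob: AscitesBlob, rng: np.random.Generator
) -> np.ndarray:
    angles = np.linspace(0, 2 * np.pi, blob.n_vertices, endpoint=False)
    radii = blob.mean_radius * (
        1.0 + blob.roughness * rng.uniform(-1.0, 1.0, size=blob.n_vertices)
    )
    ys = blob.center_y + radii * np.sin(angles)
    xs = blob.center_x + radii * np.cos(angles)
    rr, cc = skdraw.polygon(ys, xs, shape=shape)
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out


def generate(spec: PhantomSpec) -> tuple[GrayscaleImage, PhantomTruth]:
    """Render a phantom and its exact ground-truth masks.

    Compositing order: background, fascia bands (bottom band minus its
    gap), ascites, appendix; then global contrast compression about
    mid-gray, then multiplicative log-normal speckle, then clip to
    [0, 255].  The same seed always yields the same raster bit-for-bit.
    """
    _validate(spec)
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    canvas = np.full(shape, float(spec.background))

    fascia_px = np.zeros(shape, dtype=bool)
    for i, band in enumerate(spec.fascia_rows):
        y0 = max(0, band.y_center - band.thickness // 2)
        y1 = min(spec.height, y0 + band.thickness)
        band_px = np.zeros(shape, dtype=bool)
        band_px[y0:y1, :] = True
        if i == len(spec.fascia_rows) - 1 and spec.gap[1] > 0:
            gx, gw = spec.gap
            band_px[:, gx : gx + gw] = False
        canvas[band_px] = band.brightness
        fascia_px |= band_px

    ascites_px = np.zeros(shape, dtype=bool)
    if spec.ascites is not None:
        ascites_px = _ascites_mask(shape, spec.ascites, rng)
        canvas[ascites_px] = spec.ascites.brightness

    appendix_px = np.zeros(shape, dtype=bool)
    if spec.appendix is not None:
        appendix_px = _ellipse_mask(shape, spec.appendix)
        canvas[appendix_px] = spec.appendix.brightness

    if spec.contrast < 1.0:
        canvas = 128.0 + (canvas - 128.0) * spec.contrast
    if spec.speckle_sigma > 0:
        canvas = canvas * rng.lognormal(0.0, spec.speckle_sigma, size=shape)
    img = GrayscaleImage(np.clip(np.rint(canvas), 0, 255).astype(np.uint8))

    truth = PhantomTruth(
        appendix_mask=BinaryImage(appendix_px.astype(np.uint8)),
        fascia_mask=BinaryImage((fascia_px & ~ascites_px & ~appendix_px).astype(np.uint8)),
        ascites_mask=BinaryImage((ascites_px & ~appendix_px).astype(np.uint8)),
    )
    return img, truth


@dataclass(frozen=True)
class OverlapScores:
    """Region-overlap agreement between a predicted and a truth mask."""

    iou: float
    dice: float

    @property
    def success(self) -> bool:
        """Extraction counts as a success when IoU >= 0.5."""
        return self.iou >= 0.5


def evaluate(pred: BinaryImage, truth: BinaryImage) -> OverlapScores:
    """Intersection-over-union and Dice between two same-shape masks."""
    if pred.shape != truth.shape:
        raise DimensionError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    a = pred.as_bool()
    b = truth.as_bool()
    inter = int((a & b).sum())
    union = int((a | b).sum())
    total = int(a.sum()) + int(b.sum())
    iou = inter / union if union else 1.0
    dice = 2.0 * inter / total if total else 1.0
    return OverlapScores(iou=iou, dice=dice)


def default_battery(
    n: int = DEFAULT_BATTERY_SIZE, base_seed: int = 0
) -> list[PhantomSpec]:
    """The documented default phantom suite.

    ``n`` phantoms at speckle sigma 0.15 with the bottom-band gap width
    cycling through 0..60 px, the ascites distractor present in every
    second phantom, and seeded jitter of the appendix/ascites geometry
    and the gap position.  Phantom i is fully determined by
    ``base_seed + i``.
    """
    specs = []
    for i in range(n):
        seed = base_seed + i
        rng = np.random.default_rng(seed ^ 0x5EED)  # geometry jitter stream
        gap_width = (i % 7) * 10
        gap_start = int(rng.integers(180, 281))
        app_x = float(rng.uniform(150, 360))
        app = AppendixBlob(
            center_x=app_x,
            center_y=float(rng.uniform(250, 330)),
            semi_major=float(rng.uniform(45, 60)),
            semi_minor=float(rng.uniform(18, 28)),
            angle_deg=float(rng.uniform(-30, 30)),
            brightness=int(rng.integers(25, 36)),
        )
        ascites = None
        if i % 2 == 1:
            asc_x = app_x + 155 if app_x < 255 else app_x - 155
            ascites = AscitesBlob(
                center_x=float(np.clip(asc_x, 60, 452)),
                center_y=float(rng.uniform(250, 330)),
                mean_radius=float(rng.uniform(35, 50)),
                roughness=0.45,
                brightness=int(rng.integers(30, 41)),
            )
        specs.append(
            PhantomSpec(
                gap=(gap_start, gap_width),
                appendix=app,
                ascites=ascites,
                speckle_sigma=DEFAULT_SPECKLE_SIGMA,
                seed=seed,
            )
        )
    return specs


def spec_to_dict(spec: PhantomSpec) -> dict:
    """JSON-serializable form of a spec (used by the battery manifest)."""
    return dataclasses.asdict(spec)
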