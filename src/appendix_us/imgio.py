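"""Image input/output and the pipeline's core raster types.

Coordinate convention (used everywhere in this package): ``(x, y)`` means
``(column, row)``, 0-based, with ``y`` increasing downward, so "below the
fascia" always means larger ``y``.  Arrays are indexed ``pixels[y, x]``.

Grayscale conversion of color inputs uses the ITU-R BT.601 luma weights
``Y = 0.299 R + 0.587 G + 0.114 B`` rounded half-up to an integer.
Rasters with more than 8 bits per sample (16-bit TIFF/PNG, DICOM) are
linearly rescaled from their observed min/max to [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import DimensionError, ImageFormatError

#: ITU-R BT.601 luma weights for (R, G, B).
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

_DICOM_SUFFIXES = {".dcm", ".dicom"}


@dataclass
class GrayscaleImage:
    """2-D 8-bit brightness raster, the pipeline's working object.

    Parameters
    ----------
    pixels
        2-D array of integer brightness values in [0, 255]; stored as uint8.
    pixel_spacing
        Optional physical size of one pixel in mm (isotropic), > 0.
    """

    pixels: np.ndarray
    pixel_spacing: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.size == 0:
            raise DimensionError(
                f"grayscale raster must be 2-D and non-empty, got shape {arr.shape}"
            )
        if arr.dtype != np.uint8:
            if np.any((arr < 0) | (arr > 255)):
                raise ValueError("brightness values must lie in [0, 255]")
            arr = np.round(arr).astype(np.uint8)
        self.pixels = arr
        if self.pixel_spacing is not None:
            self.pixel_spacing = float(self.pixel_spacing)
            if not self.pixel_spacing > 0:
                raise ValueError("pixel_spacing must be > 0 mm")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryImage:
    """2-D {0,1} mask with the same (row, column) semantics as
    :class:`GrayscaleImage`."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.mask)
        if arr.ndim != 2 or arr.size == 0:
            raise DimensionError(
                f"binary mask must be 2-D and non-empty, got shape {arr.shape}"
            )
        if arr.dtype == bool:
            arr = arr.astype(np.uint8)
        elif not np.isin(arr, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.mask = arr.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.mask.shape[0]

    @property
    def width(self) -> int:
        return self.mask.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def as_bool(self) -> np.ndarray:
        return self.mask.astype(bool)

    @property
    def count(self) -> int:
        """Number of foreground pixels."""
        return int(self.mask.sum())


def _to_luma(arr: np.ndarray) -> np.ndarray:
    r, g, b = (arr[..., i].astype(np.float64) for i in range(3))
    wr, wg, wb = LUMA_WEIGHTS
    return np.floor(wr * r + wg * g + wb * b + 0.5)


def _rescale_to_8bit(arr: np.ndarray) -> np.ndarray:
    """Linearly map the observed data range onto [0, 255]."""
    arr = arr.astype(np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros_like(arr)
    return np.floor((arr - lo) * 255.0 / (hi - lo) + 0.5)


def _read_dicom(path: Path) -> GrayscaleImage:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array
    if arr.ndim != 2:
        raise DimensionError(f"expected single-frame DICOM, got shape {arr.shape}")
    spacing = None
    tag = ds.get("PixelSpacing")
    if tag is not None and len(tag) >= 1:
        spacing = float(tag[0])  # isotropic assumption; row spacing
    if arr.dtype != np.uint8:
        arr = _rescale_to_8bit(arr)
    return GrayscaleImage(arr, pixel_spacing=spacing)


def read_image(path: str | Path) -> GrayscaleImage:
    """Read PNG/BMP/TIFF (or DICOM) and normalize to 8-bit grayscale.

    Color images are converted with the BT.601 luma weights; rasters deeper
    than 8 bits are linearly rescaled to [0, 255] from their observed range.
    DICOM ``PixelSpacing`` is propagated as ``pixel_spacing`` when present.
    """
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"no such file: {path}")
    try:
        if path.suffix.lower() in _DICOM_SUFFIXES:
            return _read_dicom(path)
        arr = iio.imread(path)
    except DimensionError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalize reader errors
        raise ImageFormatError(f"cannot read {path} as a raster image: {exc}") from exc
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[..., :3]
        if arr.shape[2] == 3:
            arr = np.clip(_to_luma(arr), 0, 255).astype(np.uint8)
        elif arr.shape[2] == 1:
            arr = arr[..., 0]
        else:
            raise ImageFormatError(f"unsupported channel count {arr.shape[2]} in {path}")
    if arr.ndim != 2 or arr.size == 0:
        raise DimensionError(f"zero-sized or non-2-D raster in {path}")
    if arr.dtype != np.uint8 and (arr.dtype.kind != "u" or arr.dtype.itemsize > 1):
        if np.any(arr > 255) or np.any(arr < 0) or arr.dtype.kind == "f":
            arr = _rescale_to_8bit(arr)
    return GrayscaleImage(arr)


def write_mask(mask: BinaryImage, path: str | Path) -> None:
    """Write a {0,1} mask as an 8-bit single-channel PNG (0=black, 1=white)."""
    iio.imwrite(Path(path), (mask.mask * 255).astype(np.uint8))


def write_grayscale(img: GrayscaleImage, path: str | Path) -> None:
    """Write an 8-bit grayscale raster (used for per-stage debug dumps)."""
    iio.imwrite(Path(path), img.pixels)


def binarize_at(img: GrayscaleImage, threshold: float = 128) -> BinaryImage:
    """Threshold a grayscale raster (``>= threshold`` → 1); round-trip
    helper for masks written by :func:`write_mask`."""
    return BinaryImage((img.pixels >= threshold).astype(np.uint8))
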