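"""Core raster types and lossless image I/O.

The pipeline works on 8-bit grayscale fundus fluorescein angiography (FFA)
frames and binary microaneurysm (MA) masks.  Everything downstream assumes
the conventions fixed here: row-major, 0-based ``(row, col)`` indexing with
the origin at the top-left; grey levels are integers in ``[0, 255]``
(``scale="8bit"``) or reals in ``[0, 1]`` (``scale="unit"``); mask labels are
``0`` (background, which includes vessels) and ``1`` (MA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import ShapeError, ValidationError

__all__ = [
    "GrayImage",
    "MaskImage",
    "ProbabilityMap",
    "read_gray_image",
    "read_mask",
    "write_gray_image",
    "write_mask",
    "round_half_away",
]


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with ties going away from zero.

    This (not banker's rounding) is the convention used whenever a real-valued
    intensity is quantized back to an 8-bit grey level.
    """
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class GrayImage:
    """A 2-D single-channel intensity raster.

    Parameters
    ----------
    pixels
        2-D array of grey levels.  Integer dtype for ``scale="8bit"``
        (values in ``[0, 255]``), floating dtype for ``scale="unit"``
        (values in ``[0, 1]``).
    scale
        ``"8bit"`` or ``"unit"``.
    """

    pixels: np.ndarray
    scale: str = "8bit"

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValidationError(
                f"GrayImage requires a 2-D raster with height, width >= 1; got shape {arr.shape}"
            )
        if self.scale == "8bit":
            if not np.issubdtype(arr.dtype, np.integer):
                arr = arr.astype(np.int64)
            if arr.min() < 0 or arr.max() > 255:
                raise ValidationError(
                    f"8-bit intensities must lie in [0, 255]; got range [{arr.min()}, {arr.max()}]"
                )
            arr = arr.astype(np.uint8)
        elif self.scale == "unit":
            arr = arr.astype(np.float64)
            if arr.min() < 0.0 or arr.max() > 1.0:
                raise ValidationError(
                    f"unit-scale intensities must lie in [0, 1]; got range [{arr.min()}, {arr.max()}]"
                )
        else:
            raise ValidationError(f"unknown scale {self.scale!r}; expected '8bit' or 'unit'")
        object.__setattr__(self, "pixels", arr)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def i_min(self) -> int | float:
        return self.pixels.min()

    @property
    def i_max(self) -> int | float:
        return self.pixels.max()

    def to_unit(self) -> "GrayImage":
        if self.scale == "unit":
            return self
        return GrayImage(self.pixels.astype(np.float64) / 255.0, scale="unit")

    def to_8bit(self) -> "GrayImage":
        """Exact rescale to 8-bit, rounding half away from zero."""
        if self.scale == "8bit":
            return self
        return GrayImage(round_half_away(self.pixels * 255.0).astype(np.uint8), scale="8bit")


@dataclass(frozen=True)
class MaskImage:
    """A binary label raster aligned to a :class:`GrayImage`.

    Labels: 0 = background (includes vessels), 1 = microaneurysm.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValidationError(
                f"MaskImage requires a 2-D raster with height, width >= 1; got shape {arr.shape}"
            )
        values = np.unique(arr)
        if not set(values.tolist()) <= {0, 1}:
            raise ValidationError(
                f"mask labels must be a subset of {{0, 1}}; found values {sorted(values.tolist())}"
            )
        object.__setattr__(self, "labels", arr.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    def check_aligned(self, img: GrayImage) -> None:
        if (self.height, self.width) != (img.height, img.width):
            raise ShapeError(
                f"mask {self.height}x{self.width} does not match image {img.height}x{img.width}"
            )


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-pixel class probabilities over {background, MA}.

    ``probs`` has shape ``(H, W, 2)``; each pixel's probabilities are
    nonnegative and sum to 1 within 1e-6.
    """

    probs: np.ndarray
    _tol: float = field(default=1e-6, repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.probs, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[2] != 2:
            raise ValidationError(f"ProbabilityMap requires shape (H, W, 2); got {arr.shape}")
        if arr.min() < -self._tol:
            raise ValidationError("probabilities must be nonnegative")
        sums = arr.sum(axis=2)
        if np.abs(sums - 1.0).max() > self._tol:
            raise ValidationError(
                f"per-pixel probabilities must sum to 1 within {self._tol}; "
                f"max deviation {np.abs(sums - 1.0).max():.3g}"
            )
        object.__setattr__(self, "probs", arr)

    @property
    def height(self) -> int:
        return self.probs.shape[0]

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def argmax_mask(self) -> MaskImage:
        return MaskImage(np.argmax(self.probs, axis=2).astype(np.uint8))


def _to_gray_2d(arr: np.ndarray) -> np.ndarray:
    """Collapse an (H, W[, C]) raster to a 2-D luminance array (original dtype range)."""
    if arr.ndim == 3:
        if arr.shape[2] == 2:  # gray + alpha
            arr = arr[:, :, 0]
        elif arr.shape[2] in (3, 4):
            rgb = arr[:, :, :3].astype(np.float64)
            arr = round_half_away(0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2])
        else:
            raise ValidationError(f"unsupported channel count {arr.shape[2]}")
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2-D raster, got ndim={arr.ndim}")
    return arr


def read_gray_image(path: str | Path) -> GrayImage:
    """Read a PNG/TIFF raster as an 8-bit grayscale image.

    RGB inputs are converted to luminance; an alpha channel is discarded;
    16-bit rasters are linearly rescaled to the 8-bit range.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if raw.size == 0:
        raise ValidationError(f"zero-sized raster in {path}")
    arr = _to_gray_2d(np.asarray(raw))
    if arr.dtype == np.uint16 or (np.issubdtype(arr.dtype, np.integer) and arr.max() > 255):
        arr = round_half_away(arr.astype(np.float64) * (255.0 / 65535.0))
    return GrayImage(arr.astype(np.int64), scale="8bit")


def read_mask(path: str | Path) -> MaskImage:
    """Read a binary mask raster; {0, 255} files are mapped to {0, 1}.

    Any value outside {0, 1} / {0, 255} is rejected with a
    :class:`ValidationError` naming the offending values.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read mask {path}: {exc}") from exc
    arr = np.asarray(raw)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    values = set(np.unique(arr).tolist())
    if values <= {0, 1}:
        labels = arr.astype(np.uint8)
    elif values <= {0, 255}:
        labels = (arr > 0).astype(np.uint8)
    else:
        bad = sorted(values - {0, 1, 255})
        raise ValidationError(
            f"mask {path} contains values outside {{0,1}}/{{0,255}}: {bad if bad else sorted(values)}"
        )
    return MaskImage(labels)


def write_gray_image(img: GrayImage, path: str | Path) -> None:
    """Write an image as lossless 8-bit grayscale PNG.

    Round-trip contract: ``read_gray_image(path)`` after writing an
    8-bit-scale image reproduces it bit-exactly.  Unit-scale images are
    rescaled to 8-bit first (round half away from zero).
    """
    path = Path(path)
    arr = img.to_8bit().pixels
    try:
        iio.imwrite(path, arr, extension=".png" if path.suffix == "" else None)
    except OSError as exc:
        raise IOError(f"cannot write image {path}: {exc}") from exc


def write_mask(mask: MaskImage, path: str | Path) -> None:
    """Write a mask as a {0, 255} PNG (viewable; re-read maps back to {0, 1})."""
    path = Path(path)
    try:
        iio.imwrite(path, (mask.labels * np.uint8(255)))
    except OSError as exc:
        raise IOError(f"cannot write mask {path}: {exc}") from exc
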