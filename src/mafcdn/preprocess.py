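"""FFA image enhancement: histogram stretching then Gaussian filtering.

Raw angiography frames are low-contrast and noisy.  The two-stage
enhancement first linearly stretches the occupied intensity range
``[I_min, I_max]`` onto a target range ``[G_min, G_max]`` (contrast between
the tiny bright MA spots and the dark background), then convolves with a
normalized Gaussian kernel to suppress pixel noise.  Both transforms are
pure functions of the input image and their config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, ValidationError
from .image_core import GrayImage, round_half_away

__all__ = [
    "StretchConfig",
    "GaussianConfig",
    "histogram_stretch",
    "gaussian_kernel",
    "gaussian_filter",
    "preprocess_pipeline",
    "preprocess_or_passthrough",
]

log = logging.getLogger(__name__)


def default_kernel_size(sigma: float) -> int:
    """Square truncation window covering ~3-sigma support: ``2*ceil(3*sigma)+1``."""
    return 2 * int(np.ceil(3.0 * sigma)) + 1


@dataclass(frozen=True)
class StretchConfig:
    """Target grey-level range for histogram stretching."""

    g_min: int = 0
    g_max: int = 255

    def __post_init__(self) -> None:
        if not (0 <= self.g_min < self.g_max <= 255):
            raise ValidationError(
                f"require 0 <= g_min < g_max <= 255; got ({self.g_min}, {self.g_max})"
            )


@dataclass(frozen=True)
class GaussianConfig:
    """Gaussian filter parameters: standard deviation (pixels) and odd kernel side length."""

    sigma: float = 1.0
    kernel_size: int | None = None  # None -> 2*ceil(3*sigma)+1

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValidationError(f"sigma must be positive; got {self.sigma}")
        if self.kernel_size is None:
            object.__setattr__(self, "kernel_size", default_kernel_size(self.sigma))
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValidationError(f"kernel_size must be odd and >= 1; got {self.kernel_size}")


def histogram_stretch(img: GrayImage, cfg: StretchConfig = StretchConfig()) -> GrayImage:
    """Linearly map the occupied range [I_min, I_max] onto [G_min, G_max].

    Each pixel ``I`` maps to
    ``(G_max - G_min)/(I_max - I_min) * (I - I_min) + G_min``, rounded half
    away from zero and clipped to ``[G_min, G_max]``.  A constant image makes
    the mapping undefined (zero denominator) and raises
    :class:`DegenerateInputError`.
    """
    arr = img.to_8bit().pixels.astype(np.float64)
    i_min, i_max = arr.min(), arr.max()
    if i_max == i_min:
        raise DegenerateInputError(
            f"histogram stretch undefined for a constant image (value {int(i_min)})"
        )
    # multiply before dividing: products of 8-bit values are exact in float64,
    # so half-integer ties round correctly
    out = (arr - i_min) * (cfg.g_max - cfg.g_min) / (i_max - i_min) + cfg.g_min
    out = np.clip(round_half_away(out), cfg.g_min, cfg.g_max)
    return GrayImage(out.astype(np.int64), scale="8bit")


def gaussian_kernel(cfg: GaussianConfig) -> np.ndarray:
    """The l x l discrete Gaussian kernel, normalized to sum exactly 1.

    Weights are proportional to ``exp(-(x^2 + y^2) / (2 sigma^2))`` on the
    integer offset grid ``[-(l-1)/2, (l-1)/2]^2``.  The continuous
    normalization prefactor cancels under the sum-to-1 renormalization.
    """
    half = (cfg.kernel_size - 1) // 2
    offsets = np.arange(-half, half + 1, dtype=np.float64)
    x, y = np.meshgrid(offsets, offsets, indexing="ij")
    w = np.exp(-(x**2 + y**2) / (2.0 * cfg.sigma**2))
    return w / w.sum()


def gaussian_filter(img: GrayImage, cfg: GaussianConfig = GaussianConfig()) -> GrayImage:
    """Convolve with the normalized Gaussian kernel, reflect padding at borders.

    Border mode is mirror-without-edge-repeat.  The filtered image is rounded
    half away from zero and clipped to [0, 255]; a constant image is a fixed
    point (the kernel sums to 1).
    """
    arr = img.to_8bit().pixels.astype(np.float64)
    kernel = gaussian_kernel(cfg)
    # symmetric kernel: correlation == convolution
    out = ndimage.correlate(arr, kernel, mode="mirror")
    out = np.clip(round_half_away(out), 0, 255)
    return GrayImage(out.astype(np.int64), scale="8bit")


def preprocess_pipeline(
    img: GrayImage,
    stretch: StretchConfig = StretchConfig(),
    gaussian: GaussianConfig = GaussianConfig(),
) -> GrayImage:
    """Histogram stretching followed by Gaussian filtering, in that order."""
    return gaussian_filter(histogram_stretch(img, stretch), gaussian)


def preprocess_or_passthrough(
    img: GrayImage,
    stretch: StretchConfig = StretchConfig(),
    gaussian: GaussianConfig = GaussianConfig(),
    name: str = "<image>",
) -> GrayImage:
    """Batch-level wrapper: a constant (blank) frame is logged and passed
    through unchanged instead of aborting the run."""
    try:
        return preprocess_pipeline(img, stretch, gaussian)
    except DegenerateInputError:
        log.warning("constant image %s: preprocessing passed through unchanged", name)
        return img
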