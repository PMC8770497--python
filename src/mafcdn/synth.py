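"""Synthetic fundus-fluorescein-angiography scene generator.

Real FFA frames show a dark, unevenly illuminated background, bright
curvilinear vessel trees, and — in diabetic retinopathy — microaneurysms:
tiny (few-pixel) bright round leakage spots that sit close to vessels and
have limited contrast against them.  MA pixels are a vanishing fraction of
the frame, so the segmentation problem is dominated by class imbalance.

This module generates grayscale scenes with those statistics plus paired
ground-truth masks, so training, evaluation and ablation all run with no
external data.  Every pixel is a deterministic function of the config seed.

What is emulated: frame geometry, dark background with a smooth illumination
field, bright vessel strokes, small radially-decaying MA discs placed near
vessels, additive Gaussian sensor noise, and a global contrast-compression
knob that mimics washed-out raw frames.  What is not: real vessel-tree
topology, lesion texture, phase-dependent fluorescein dynamics, or any
photometric calibration against real angiographs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import GenerationError, ValidationError
from .image_core import GrayImage, MaskImage, write_gray_image, write_mask

__all__ = [
    "SyntheticSceneConfig",
    "SyntheticSample",
    "generate_sample",
    "generate_dataset",
    "EASY",
    "HARD",
    "preset_config",
]

_VESSEL_ATTACH_DIST = 10.0  # MAs are placed within this many pixels of a vessel
_PLACE_RETRIES = 200


@dataclass(frozen=True)
class SyntheticSceneConfig:
    """Scene content and noise parameters (grey levels are 8-bit)."""

    height: int = 128
    width: int = 128
    n_vessels: int = 6
    vessel_width_range: tuple[float, float] = (1.5, 3.0)
    vessel_intensity: int = 130
    n_mas: int = 8
    ma_radius_range: tuple[float, float] = (1.0, 3.0)
    ma_peak_intensity: int = 220
    background_level: int = 30
    illumination_amp: float = 12.0
    noise_sigma: float = 4.0
    contrast_compression: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValidationError("frame must be at least 8x8")
        for v in (self.vessel_intensity, self.ma_peak_intensity, self.background_level):
            if not (0 <= v <= 255):
                raise ValidationError(f"grey levels must lie in [0, 255]; got {v}")
        if self.ma_peak_intensity <= self.vessel_intensity:
            raise ValidationError(
                "ma_peak_intensity must exceed vessel_intensity so MA spots stay "
                "brighter than the vessel-adjacent background"
            )
        if not (0.0 < self.contrast_compression <= 1.0):
            raise ValidationError("contrast_compression must be in (0, 1]")
        if self.n_vessels < 0 or self.n_mas < 0 or self.noise_sigma < 0:
            raise ValidationError("counts and noise sigma must be nonnegative")
        lo, hi = self.ma_radius_range
        if not (0.5 <= lo <= hi):
            raise ValidationError(f"invalid ma_radius_range {self.ma_radius_range}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["vessel_width_range"] = list(self.vessel_width_range)
        d["ma_radius_range"] = list(self.ma_radius_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSceneConfig":
        d = dict(d)
        d["vessel_width_range"] = tuple(d["vessel_width_range"])
        d["ma_radius_range"] = tuple(d["ma_radius_range"])
        return cls(**d)


# difficulty presets: `easy` for smoke tests, `hard` for ablation demonstrations
EASY = SyntheticSceneConfig(noise_sigma=3.0, contrast_compression=1.0, ma_peak_intensity=230)
HARD = SyntheticSceneConfig(noise_sigma=8.0, contrast_compression=0.4, ma_peak_intensity=200)


def preset_config(name: str, **overrides) -> SyntheticSceneConfig:
    base = {"easy": EASY, "hard": HARD}.get(name)
    if base is None:
        raise ValidationError(f"unknown difficulty preset {name!r}; valid: easy, hard")
    return replace(base, **overrides)


@dataclass(frozen=True)
class SyntheticSample:
    """A generated image, its MA mask, and the ground-truth disc list."""

    image: GrayImage
    mask: MaskImage
    ma_centers: list  # of (row, col, radius)


def _illumination(rng: np.random.Generator, h: int, w: int, amp: float) -> np.ndarray:
    """Smooth low-frequency illumination field: a coarse random grid upsampled."""
    coarse = rng.normal(0.0, amp, size=(4, 4))
    return ndimage.zoom(coarse, (h / 4, w / 4), order=3, mode="nearest")


def _draw_vessels(
    rng: np.random.Generator, canvas: np.ndarray, cfg: SyntheticSceneConfig
) -> np.ndarray:
    """Stamp smooth random curvilinear strokes; returns a boolean vessel map."""
    h, w = canvas.shape
    vessel = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(cfg.n_vessels):
        # random walk with slowly drifting heading, starting on a border
        side = rng.integers(4)
        if side == 0:
            r, c, ang = 0.0, rng.uniform(0, w), rng.uniform(0.25, 0.75) * np.pi
        elif side == 1:
            r, c, ang = h - 1.0, rng.uniform(0, w), rng.uniform(-0.75, -0.25) * np.pi
        elif side == 2:
            r, c, ang = rng.uniform(0, h), 0.0, rng.uniform(-0.25, 0.25) * np.pi
        else:
            r, c, ang = rng.uniform(0, h), w - 1.0, rng.uniform(0.75, 1.25) * np.pi
        width = rng.uniform(*cfg.vessel_width_range)
        n_steps = int(1.5 * max(h, w))
        for _ in range(n_steps):
            rad = width / 2.0
            r0, r1 = int(max(0, np.floor(r - rad - 1))), int(min(h, np.ceil(r + rad + 2)))
            c0, c1 = int(max(0, np.floor(c - rad - 1))), int(min(w, np.ceil(c + rad + 2)))
            if r0 < r1 and c0 < c1:
                d2 = (yy[r0:r1, c0:c1] - r) ** 2 + (xx[r0:r1, c0:c1] - c) ** 2
                vessel[r0:r1, c0:c1] |= d2 <= rad * rad
            ang += rng.normal(0.0, 0.15)
            r += np.sin(ang)
            c += np.cos(ang)
            if not (-2 < r < h + 2 and -2 < c < w + 2):
                break
    canvas[vessel] = np.maximum(canvas[vessel], cfg.vessel_intensity)
    return vessel


def _place_mas(
    rng: np.random.Generator, vessel: np.ndarray, cfg: SyntheticSceneConfig
) -> list[tuple[int, int, float]]:
    h, w = vessel.shape
    vr, vc = np.nonzero(vessel)
    centers: list[tuple[int, int, float]] = []
    for _ in range(cfg.n_mas):
        placed = False
        for _ in range(_PLACE_RETRIES):
            radius = rng.uniform(*cfg.ma_radius_range)
            margin = int(np.ceil(radius)) + 1
            if len(vr):
                # preferential attachment: jitter around a random vessel pixel
                k = rng.integers(len(vr))
                dist = rng.uniform(2.0, _VESSEL_ATTACH_DIST)
                theta = rng.uniform(0, 2 * np.pi)
                r = int(round(vr[k] + dist * np.sin(theta)))
                c = int(round(vc[k] + dist * np.cos(theta)))
            else:
                r = int(rng.integers(margin, h - margin))
                c = int(rng.integers(margin, w - margin))
            if not (margin <= r < h - margin and margin <= c < w - margin):
                continue
            if all(
                (r - r2) ** 2 + (c - c2) ** 2 > (radius + rad2 + 1.0) ** 2
                for r2, c2, rad2 in centers
            ):
                centers.append((r, c, float(radius)))
                placed = True
                break
        if not placed:
            raise GenerationError(
                f"could not place MA {len(centers) + 1}/{cfg.n_mas} without overlap "
                f"after {_PLACE_RETRIES} retries on a {h}x{w} frame"
            )
    return centers


def _stamp_mas(
    canvas: np.ndarray, centers: list[tuple[int, int, float]], cfg: SyntheticSceneConfig
) -> np.ndarray:
    h, w = canvas.shape
    mask = np.zeros((h, w), dtype=np.uint8)
    for r, c, radius in centers:
        m = int(np.ceil(radius)) + 1
        yy, xx = np.mgrid[r - m:r + m + 1, c - m:c + m + 1]
        d2 = (yy - r) ** 2 + (xx - c) ** 2
        inside = d2 <= radius * radius
        # bright disc with a gentle radial falloff (edge keeps >= half the peak)
        profile = cfg.ma_peak_intensity * (1.0 - 0.5 * d2 / (radius * radius))
        win = canvas[r - m:r + m + 1, c - m:c + m + 1]
        win[inside] = np.maximum(win[inside], profile[inside])
        mask[r - m:r + m + 1, c - m:c + m + 1][inside] = 1
    return mask


def generate_sample(cfg: SyntheticSceneConfig) -> SyntheticSample:
    """Render one scene; deterministic given ``cfg.seed``.

    Stages: flat background + smooth illumination field; vessel strokes;
    MA discs (preferentially within 10 px of a vessel, non-overlapping, fully
    inside the frame); additive Gaussian noise; contrast compression toward
    mid-grey; clip to [0, 255].  The mask marks exactly the MA discs
    (a pixel is inside a disc iff its center lies within the Euclidean
    radius); vessels belong to the background class.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height, cfg.width
    canvas = np.full((h, w), float(cfg.background_level))
    if cfg.illumination_amp > 0:
        canvas += _illumination(rng, h, w, cfg.illumination_amp)
    vessel = _draw_vessels(rng, canvas, cfg)
    centers = _place_mas(rng, vessel, cfg)
    mask = _stamp_mas(canvas, centers, cfg)
    if cfg.noise_sigma > 0:
        canvas += rng.normal(0.0, cfg.noise_sigma, size=canvas.shape)
    if cfg.contrast_compression < 1.0:
        canvas = 128.0 + cfg.contrast_compression * (canvas - 128.0)
    canvas = np.clip(np.floor(canvas + 0.5), 0, 255).astype(np.int64)
    return SyntheticSample(
        image=GrayImage(canvas, scale="8bit"),
        mask=MaskImage(mask),
        ma_centers=centers,
    )


def generate_dataset(
    cfg: SyntheticSceneConfig,
    n_train: int,
    n_val: int,
    n_test: int,
    out_dir: str | Path,
) -> dict:
    """Write image/mask PNG pairs under train/ val/ test/ plus a JSON manifest.

    Per-sample seeds are derived disjointly from ``cfg.seed`` via a seed
    sequence, so the master seed determines every pixel and regeneration from
    the manifest seeds is bit-identical.  The split counts mirror the
    train/val/test protocol (e.g. 8:1:1 at reduced scale).
    """
    if min(n_train, n_val, n_test) < 0 or n_train + n_val + n_test == 0:
        raise ValidationError("split counts must be >= 0 with at least one > 0")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc

    total = n_train + n_val + n_test
    seeds = [int(s % (2**31)) for s in np.random.SeedSequence(cfg.seed).generate_state(total)]
    manifest: dict = {"config": cfg.to_dict(), "splits": {}}
    i = 0
    for split, count in (("train", n_train), ("val", n_val), ("test", n_test)):
        split_dir = out_dir / split
        split_dir.mkdir(exist_ok=True)
        entries = []
        for j in range(count):
            sample_cfg = replace(cfg, seed=seeds[i])
            sample = generate_sample(sample_cfg)
            img_path = split_dir / f"{j:04d}_img.png"
            mask_path = split_dir / f"{j:04d}_mask.png"
            write_gray_image(sample.image, img_path)
            write_mask(sample.mask, mask_path)
            entries.append(
                {
                    "image": str(img_path.relative_to(out_dir)),
                    "mask": str(mask_path.relative_to(out_dir)),
                    "seed": seeds[i],
                    "n_mas": len(sample.ma_centers),
                }
            )
            i += 1
        manifest["splits"][split] = entries
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
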