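"""Training, prediction, evaluation and ablation orchestration.

The harness is the executable embodiment of the two-step pipeline: optional
preprocessing (histogram stretching + Gaussian filtering), an FC-DenseNet
optimized with the focal (or cross-entropy) loss, per-epoch validation on
MIoU with best-checkpoint selection, and the six-metric evaluation.  The
three-arm ablation grid (preprocessing-only, focal-only, both) reproduces
the ablation design at synthetic scale.

Determinism contract: a persisted run config re-launched on the same data in
single-worker mode reproduces the per-epoch log bit-for-bit — every random
draw (weight init, shuffling, dropout, crops) derives from the master seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ShapeError, ValidationError
from .image_core import (
    GrayImage,
    MaskImage,
    read_gray_image,
    read_mask,
    write_mask,
)
from .metrics import (
    METRIC_NAMES,
    AggregateReport,
    MetricsReport,
    aggregate,
    compute_metrics,
    confusion,
    write_reports,
)
from .network import (
    ArchitectureConfig,
    FCDenseNet,
    FocalConfig,
    focal_loss_with_logit_grad,
    preset,
    softmax_logits,
)
from .nn.layers import DTYPE, RMSProp
from .preprocess import GaussianConfig, StretchConfig, preprocess_or_passthrough

__all__ = [
    "LossSpec",
    "PreprocessSpec",
    "OptimizerSpec",
    "RunConfig",
    "AblationArm",
    "default_ablation_grid",
    "train",
    "TrainResult",
    "load_checkpoint",
    "predict",
    "evaluate",
    "ablate",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LossSpec:
    name: str = "focal"  # "focal" | "cross_entropy"
    alpha_ma: float = 0.25
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if self.name not in ("focal", "cross_entropy"):
            raise ValidationError(f"loss must be 'focal' or 'cross_entropy'; got {self.name!r}")

    def resolve(self) -> tuple[np.ndarray, float]:
        """(per-class alpha over {background, MA}, gamma) for the fused loss."""
        if self.name == "cross_entropy":
            return np.array([1.0, 1.0]), 0.0
        return FocalConfig(self.alpha_ma, self.gamma).alpha_t, self.gamma


@dataclass(frozen=True)
class PreprocessSpec:
    enabled: bool = True
    g_min: int = 0
    g_max: int = 255
    sigma: float = 1.0
    kernel_size: int | None = None

    def configs(self) -> tuple[StretchConfig, GaussianConfig]:
        return StretchConfig(self.g_min, self.g_max), GaussianConfig(self.sigma, self.kernel_size)


@dataclass(frozen=True)
class OptimizerSpec:
    name: str = "rmsprop"
    lr: float = 1e-3
    lr_decay: float = 0.995  # exponential per-epoch decay

    def build(self) -> RMSProp:
        if self.name != "rmsprop":
            raise ValidationError(f"unsupported optimizer {self.name!r}")
        return RMSProp(lr=self.lr, lr_decay=self.lr_decay)


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one training run."""

    model: str | ArchitectureConfig = "tiny"
    loss: LossSpec = field(default_factory=LossSpec)
    preprocess: PreprocessSpec = field(default_factory=PreprocessSpec)
    optimizer: OptimizerSpec = field(default_factory=OptimizerSpec)
    epochs: int = 15
    batch_size: int = 4
    crop_size: int | None = None  # None: whole frame (must be divisible)
    patience: int = 20  # early stopping on val MIoU
    stop_at_val_miou: float | None = None  # optional early-success stop
    seed: int = 0

    def arch(self) -> ArchitectureConfig:
        return preset(self.model) if isinstance(self.model, str) else self.model

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model"] = self.model if isinstance(self.model, str) else self.model.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("model"), dict):
            d["model"] = ArchitectureConfig.from_dict(d["model"])
        for key, typ in (
            ("loss", LossSpec),
            ("preprocess", PreprocessSpec),
            ("optimizer", OptimizerSpec),
        ):
            if isinstance(d.get(key), dict):
                d[key] = typ(**d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


# -- data loading ------------------------------------------------------------


def _load_split(split_dir: Path, spec: PreprocessSpec) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Load `NNNN_img.png` / `NNNN_mask.png` pairs, preprocess, scale to [0,1]."""
    img_paths = sorted(split_dir.glob("*_img.png"))
    if not img_paths:
        raise ValidationError(f"no *_img.png files in {split_dir}")
    names, imgs, masks = [], [], []
    stretch, gauss = spec.configs()
    for img_path in img_paths:
        mask_path = split_dir / img_path.name.replace("_img.png", "_mask.png")
        if not mask_path.exists():
            raise ValidationError(f"missing mask for {img_path.name}")
        img = read_gray_image(img_path)
        mask = read_mask(mask_path)
        if (mask.height, mask.width) != (img.height, img.width):
            raise ShapeError(
                f"{img_path.name}: image {img.height}x{img.width} vs mask "
                f"{mask.height}x{mask.width}"
            )
        if spec.enabled:
            img = preprocess_or_passthrough(img, stretch, gauss, name=img_path.name)
        names.append(img_path.name)
        imgs.append(img.pixels.astype(DTYPE) / 255.0)
        masks.append(mask.labels)
    return names, np.stack(imgs), np.stack(masks)


def _pad_to_divisible(arr: np.ndarray, d: int) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = arr.shape[-2:]
    ph, pw = (-h) % d, (-w) % d
    if ph or pw:
        pad = [(0, 0)] * (arr.ndim - 2) + [(0, ph), (0, pw)]
        arr = np.pad(arr, pad, mode="reflect")
    return arr, (h, w)


# -- training ----------------------------------------------------------------


@dataclass
class TrainResult:
    best_checkpoint: Path
    final_checkpoint: Path
    log_path: Path
    config_path: Path
    history: list[dict]
    best_val_miou: float
    best_epoch: int


def _val_metrics(net: FCDenseNet, imgs: np.ndarray, masks: np.ndarray, batch: int) -> AggregateReport:
    reports = []
    for i in range(0, len(imgs), batch):
        x = imgs[i:i + batch][:, None]
        probs = net.predict_proba(x)
        pred = np.argmax(probs, axis=1).astype(np.uint8)
        for p, t in zip(pred, masks[i:i + batch]):
            reports.append(compute_metrics(confusion(MaskImage(p), MaskImage(t))))
    return aggregate(reports)


def _save_checkpoint(path: Path, net: FCDenseNet, cfg: RunConfig) -> None:
    """Self-describing checkpoint: weights + architecture + run config."""
    meta = json.dumps({"run_config": cfg.to_dict(), "arch": net.cfg.to_dict()})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **net.state_arrays())


def load_checkpoint(path: str | Path) -> tuple[FCDenseNet, RunConfig]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    arch = ArchitectureConfig.from_dict(meta["arch"])
    run_cfg = RunConfig.from_dict(meta["run_config"])
    net = FCDenseNet(arch, seed=0)
    net.load_state_arrays(state)
    return net, run_cfg


def _format_float(x: float) -> str:
    return f"{x:.10g}"


def train(cfg: RunConfig, data_dir: str | Path, out_dir: str | Path) -> TrainResult:
    """Optimize the configured loss on train/, select by val MIoU.

    Persists the best and final checkpoints, a per-epoch CSV log (only
    deterministic fields, so reruns compare bit-for-bit), and the resolved
    run config.
    """
    if cfg.epochs < 1:
        raise ValidationError("epochs must be >= 1 (nothing to train otherwise)")
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    _, train_x, train_y = _load_split(data_dir / "train", cfg.preprocess)
    _, val_x, val_y = _load_split(data_dir / "val", cfg.preprocess)
    arch = cfg.arch()
    d = arch.spatial_divisor
    crop = cfg.crop_size
    if crop is not None and crop % d:
        raise ShapeError(f"crop_size {crop} not divisible by {d}")
    if crop is None and (train_x.shape[1] % d or train_x.shape[2] % d):
        raise ShapeError(
            f"training frames {train_x.shape[1]}x{train_x.shape[2]} not divisible by {d}; "
            "set crop_size"
        )

    rng = np.random.default_rng(cfg.seed)
    net = FCDenseNet(arch, seed=int(rng.integers(2**31)))
    net.seed_dropout(int(rng.integers(2**31)))
    opt = cfg.optimizer.build()
    alpha_t, gamma = cfg.loss.resolve()
    layers = net.iter_layers()

    best_miou, best_epoch = -1.0, -1
    history: list[dict] = []
    best_path = out_dir / "checkpoint_best.npz"
    final_path = out_dir / "checkpoint_final.npz"
    n = len(train_x)
    val_x_p, _ = _pad_to_divisible(val_x, d)

    for epoch in range(cfg.epochs):
        opt.epoch = epoch
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb, yb = train_x[idx], train_y[idx]
            if crop is not None and (xb.shape[1] > crop or xb.shape[2] > crop):
                r0 = rng.integers(0, xb.shape[1] - crop + 1)
                c0 = rng.integers(0, xb.shape[2] - crop + 1)
                xb = xb[:, r0:r0 + crop, c0:c0 + crop]
                yb = yb[:, r0:r0 + crop, c0:c0 + crop]
            logits = net.forward_logits(xb[:, None], train=True)
            loss, g = focal_loss_with_logit_grad(logits, yb, alpha_t, gamma)
            net.backward(g)
            opt.step(layers)
            losses.append(loss)
        val = _val_metrics(net, val_x_p, val_y, cfg.batch_size)
        row = {
            "epoch": epoch,
            "lr": _format_float(opt.lr),
            "train_loss": _format_float(float(np.mean(losses))),
            "val_miou": _format_float(val.mean.MIoU),
            "val_f1": _format_float(val.mean.F1),
            "val_pa": _format_float(val.mean.PA),
        }
        history.append(row)
        log.info(
            "epoch %d: loss %.5f, val MIoU %.4f, F1 %.4f (%.1fs)",
            epoch, float(np.mean(losses)), val.mean.MIoU, val.mean.F1, time.time() - t0,
        )
        if val.mean.MIoU > best_miou:
            best_miou, best_epoch = val.mean.MIoU, epoch
            _save_checkpoint(best_path, net, cfg)
        if cfg.stop_at_val_miou is not None and val.mean.MIoU >= cfg.stop_at_val_miou:
            break
        if epoch - best_epoch >= cfg.patience:
            break

    _save_checkpoint(final_path, net, cfg)
    log_path = out_dir / "epochs.csv"
    pd.DataFrame(history).to_csv(log_path, index=False)
    config_path = out_dir / "run_config.json"
    cfg.save(config_path)
    return TrainResult(
        best_checkpoint=best_path,
        final_checkpoint=final_path,
        log_path=log_path,
        config_path=config_path,
        history=history,
        best_val_miou=best_miou,
        best_epoch=best_epoch,
    )


# -- inference and evaluation ------------------------------------------------


def predict(checkpoint: str | Path, images_dir: str | Path, out_dir: str | Path) -> list[Path]:
    """Write one {0,255} mask PNG per input image (argmax decoding).

    The checkpoint is self-describing: its stored preprocessing settings are
    applied, inputs are reflect-padded to the architecture's divisibility
    requirement and the prediction cropped back.  Inference is deterministic
    (dropout off, running batch-norm statistics).
    """
    net, run_cfg = load_checkpoint(checkpoint)
    images_dir, out_dir = Path(images_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = sorted(p for p in images_dir.glob("*.png") if not p.name.endswith("_mask.png"))
    if not paths:
        raise ValidationError(f"no input PNGs in {images_dir}")
    stretch, gauss = run_cfg.preprocess.configs()
    written = []
    for p in paths:
        img = read_gray_image(p)
        if run_cfg.preprocess.enabled:
            img = preprocess_or_passthrough(img, stretch, gauss, name=p.name)
        x = img.pixels.astype(DTYPE) / 255.0
        xp, (h, w) = _pad_to_divisible(x[None, None], net.cfg.spatial_divisor)
        probs = net.predict_proba(xp)[0]
        pred = np.argmax(probs, axis=0)[:h, :w].astype(np.uint8)
        out_name = p.name.replace("_img.png", "_mask.png") if p.name.endswith("_img.png") else p.name
        out_path = out_dir / out_name
        write_mask(MaskImage(pred), out_path)
        written.append(out_path)
    return written


def evaluate(
    pred_dir: str | Path, truth_dir: str | Path, out_dir: str | Path | None = None
) -> tuple[dict[str, MetricsReport], AggregateReport]:
    """Per-image six-metric reports plus mean +/- std across matched files."""
    pred_dir, truth_dir = Path(pred_dir), Path(truth_dir)
    pred_files = {p.name for p in pred_dir.glob("*_mask.png")}
    truth_files = {p.name for p in truth_dir.glob("*_mask.png")}
    orphans = pred_files ^ truth_files
    if not pred_files or orphans:
        raise ValidationError(
            f"prediction/truth filename mismatch; orphans: {sorted(orphans)}"
            if orphans
            else f"no *_mask.png files in {pred_dir}"
        )
    per_image: dict[str, MetricsReport] = {}
    for name in sorted(pred_files):
        pred = read_mask(pred_dir / name)
        truth = read_mask(truth_dir / name)
        per_image[name] = compute_metrics(confusion(pred, truth))
    agg = aggregate(list(per_image.values()))
    if out_dir is not None:
        write_reports(per_image, agg, out_dir)
    return per_image, agg


# -- ablation ----------------------------------------------------------------


@dataclass(frozen=True)
class AblationArm:
    name: str
    config: RunConfig


def default_ablation_grid(base: RunConfig) -> list[AblationArm]:
    """The three-arm design: preprocessing-only, focal-only, and both.

    All arms share the base seed and data split; only the named components
    differ.
    """
    ce = LossSpec(name="cross_entropy")
    focal = LossSpec(name="focal", alpha_ma=base.loss.alpha_ma, gamma=base.loss.gamma)
    pre_on = replace(base.preprocess, enabled=True)
    pre_off = replace(base.preprocess, enabled=False)
    return [
        AblationArm("preprocessing+net", replace(base, loss=ce, preprocess=pre_on)),
        AblationArm("net+focal", replace(base, loss=focal, preprocess=pre_off)),
        AblationArm("full", replace(base, loss=focal, preprocess=pre_on)),
    ]


def ablate(grid: list[AblationArm], data_dir: str | Path, out_dir: str | Path) -> pd.DataFrame:
    """Train and evaluate every arm under identical seed/split; emit a
    comparison table (rows = arms, columns = the six metrics as mean +/- std).

    A failing arm is recorded as failed rather than aborting the grid.
    """
    if not grid:
        raise ValidationError("ablation grid is empty")
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    results_json = {}
    for arm in grid:
        arm_dir = out_dir / arm.name.replace("+", "_")
        try:
            result = train(arm.config, data_dir, arm_dir)
            pred_dir = arm_dir / "pred_test"
            predict(result.best_checkpoint, data_dir / "test", pred_dir)
            _, agg = evaluate(pred_dir, data_dir / "test", arm_dir)
            rows.append({"model": arm.name, **agg.format_row()})
            results_json[arm.name] = {"status": "ok", **agg.as_dict()}
        except Exception as exc:  # noqa: BLE001 - failed arms are marked, not fatal
            log.error("arm %s failed: %s", arm.name, exc)
            rows.append({"model": arm.name, **{k: "failed" for k in METRIC_NAMES}})
            results_json[arm.name] = {"status": "failed", "error": str(exc)}
    table = pd.DataFrame(rows, columns=["model", *METRIC_NAMES])
    table.to_csv(out_dir / "ablation.csv", index=False)
    (out_dir / "ablation.json").write_text(json.dumps(results_json, indent=2, sort_keys=True))
    return table
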