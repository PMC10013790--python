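"""Staged training: synthetic pretraining and three domain-adaptation steps.

The pipeline trains five models. Model S learns from the synthesized
composites alone. Step I fine-tunes S on all 360 integer-degree rotations of
the annotated frames (model D) — rotation of image and mask together is a
computationally inferable labeling, so these real-image variants cost no new
annotation. Step II predicts masks for the unlabeled clip frames with model
D and fine-tunes on those pseudo-labels (model P). Step III fine-tunes P on
the few externally annotated frames, again expanded with all rotations
(model G). A Baseline trains from scratch on the Step III data only. Every
stage selects the epoch with the smallest validation loss.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import rotate as sk_rotate

from . import imgio
from .errors import ConfigError, InputError
from .framestore import Frame
from .manifest import DatasetManifest, make_row
from .metrics import binarize
from .model import UNetSegmenter
from .nn import load_checkpoint, save_checkpoint

STAGE_IDS = ("S", "D", "P", "G", "baseline")
DEFAULT_EPOCHS = {"S": 10, "D": 4, "P": 3, "G": 2, "baseline": 4}


@dataclass
class StageConfig:
    """One training stage: data, schedule, and initialization."""

    stage_id: str
    train_manifest: DatasetManifest | str | os.PathLike
    val_manifest: DatasetManifest | str | os.PathLike | None
    init_from: str | os.PathLike | None = None  # checkpoint path or None = scratch
    epochs: int = 10
    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 8
    seed: int = 0
    encoder: str = "tiny"
    online_augment: bool = False
    max_val_images: int | None = None
    out_dir: str | os.PathLike = "checkpoints"

    def __post_init__(self) -> None:
        if self.stage_id not in STAGE_IDS:
            raise ConfigError(f"stage_id must be one of {STAGE_IDS}, got {self.stage_id!r}")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")


@dataclass
class StageCheckpoint:
    """Result of a trained stage: weights plus the selection record."""

    stage_id: str
    weights_path: Path
    history: list[dict]
    selected_epoch: int
    val_loss: float


def _resolve_manifest(m) -> DatasetManifest:
    if isinstance(m, DatasetManifest):
        return m
    return DatasetManifest.load(m)


def load_dataset(
    manifest: DatasetManifest,
    max_images: int | None = None,
    seed: int = 0,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Load (images, masks) from a manifest, optionally subsampled (seeded)."""
    idx = np.arange(len(manifest))
    if max_images is not None and max_images < len(idx):
        idx = np.sort(np.random.default_rng(seed).choice(idx, max_images, replace=False))
    img_paths = manifest.image_paths()
    mask_paths = manifest.mask_paths()
    images, masks = [], []
    for i in idx:
        images.append(imgio.load_image(img_paths[i]))
        mp = mask_paths[i]
        if mp is None:
            raise InputError(f"record {i} has no mask")
        masks.append(imgio.load_mask(mp))
    return images, masks


def rotations_dataset(
    image: np.ndarray,
    mask: np.ndarray,
    out_dir: str | os.PathLike,
    online_augment: bool = False,
    stage: str = "D",
    split: str = "train",
    source_id: str = "rot",
) -> DatasetManifest:
    """All 360 integer-degree rotations (0..359) of one annotated image.

    The canvas is expanded to contain the rotated frame (zero fill for both
    image and mask); the image is interpolated bilinearly and the mask with
    nearest neighbour. Degree 0 is the original image; right-angle rotations
    are computed exactly. ``online_augment`` flags every record for strong
    augmentation on access during training.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape:
        raise InputError(f"image {image.shape[:2]} and mask {mask.shape} shapes differ")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for deg in range(360):
        if deg == 0:
            img_r, mask_r = image, mask
        elif deg % 90 == 0:
            k = deg // 90
            img_r = np.rot90(image, k, axes=(0, 1))
            mask_r = np.rot90(mask, k, axes=(0, 1))
        else:
            img_r = sk_rotate(image.astype(np.float64), deg, resize=True, order=1, cval=0.0)
            mask_r = (
                sk_rotate(mask.astype(np.float64), deg, resize=True, order=0, cval=0.0) > 0.5
            ).astype(np.uint8)
        name = f"{source_id}_{deg:03d}.png"
        imgio.save_image(out / "images" / name, img_r)
        imgio.save_mask(out / "masks" / name, mask_r)
        rows.append(
            make_row(
                id=f"{source_id}-{deg:03d}",
                image_path=f"images/{name}",
                mask_path=f"masks/{name}",
                split=split,
                stage=stage,
                domain="augment-online" if online_augment else "rotations",
                seed=deg,
            )
        )
    man = DatasetManifest.from_rows(rows, root=out)
    man.save(out / f"manifest_{source_id}.csv")
    return man


def merge_manifests(manifests: list[DatasetManifest], out_path: str | os.PathLike) -> DatasetManifest:
    """Concatenate manifests that share a root directory."""
    import pandas as pd

    roots = {str(m.root) for m in manifests}
    if len(roots) != 1:
        raise InputError("merge_manifests requires a common root")
    df = pd.concat([m.records for m in manifests], ignore_index=True)
    man = DatasetManifest(records=df, root=manifests[0].root)
    man.save(out_path)
    return man


def generate_pseudo_labels(
    model,
    frames: list[Frame],
    out_dir: str | os.PathLike,
    threshold: float = 0.5,
    split: str = "train",
) -> DatasetManifest:
    """Predict hard masks for unlabeled frames and write them as a dataset.

    The masks are the model's own thresholded probability maps — noisy where
    the model errs, which is the accepted price of pseudo-labeling.
    """
    if not frames:
        raise InputError("no frames to pseudo-label")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    from .metrics import _predict_probs_any

    rows = []
    for f in frames:
        probs = _predict_probs_any(model, f.image)
        mask = binarize(probs, threshold)
        name = f"{f.clip_id}_{f.index:05d}.png"
        imgio.save_image(out / "images" / name, f.image)
        imgio.save_mask(out / "masks" / name, mask)
        rows.append(
            make_row(
                id=f"pseudo-{f.index:05d}",
                image_path=f"images/{name}",
                mask_path=f"masks/{name}",
                split=split,
                stage="P-train" if split == "train" else "P-val",
                domain="pseudo",
                seed=f.index,
            )
        )
    man = DatasetManifest.from_rows(rows, root=out)
    man.save(out / f"manifest_{split}.csv")
    return man


def train_stage(cfg: StageConfig) -> StageCheckpoint:
    """Train one stage with SGD on the Dice+BCE loss; keep the min-val-loss epoch."""
    train_man = _resolve_manifest(cfg.train_manifest)
    if len(train_man) == 0:
        raise InputError(f"stage {cfg.stage_id}: training manifest is empty")
    X, y = load_dataset(train_man)
    X_val = y_val = None
    if cfg.val_manifest is not None:
        val_man = _resolve_manifest(cfg.val_manifest)
        if len(val_man) == 0:
            raise InputError(f"stage {cfg.stage_id}: validation manifest is empty")
        X_val, y_val = load_dataset(val_man, max_images=cfg.max_val_images, seed=cfg.seed)

    init_state = None
    if cfg.init_from not in (None, "scratch"):
        net, _ = load_checkpoint(cfg.init_from)
        init_state = net.state_dict()

    est = UNetSegmenter(
        encoder=cfg.encoder,
        epochs=cfg.epochs,
        learning_rate=cfg.learning_rate,
        momentum=cfg.momentum,
        batch_size=cfg.batch_size,
        online_augment=cfg.online_augment,
        seed=cfg.seed,
    )
    est.fit(X, y, X_val, y_val, init_state=init_state)
    out = Path(cfg.out_dir)
    ckpt_path = out / f"model_{cfg.stage_id}.npz"
    save_checkpoint(
        ckpt_path,
        est.net_,
        meta={
            "stage_id": cfg.stage_id,
            "init_from": str(cfg.init_from) if cfg.init_from not in (None, "scratch") else "scratch",
            "seed": cfg.seed,
            "selected_epoch": est.selected_epoch_,
            "val_loss": est.best_val_loss_,
            "history": est.history_,
        },
    )
    return StageCheckpoint(
        stage_id=cfg.stage_id,
        weights_path=ckpt_path,
        history=est.history_,
        selected_epoch=est.selected_epoch_,
        val_loss=est.best_val_loss_,
    )


_TOP_KEYS = {"workdir", "encoder", "seed", "learning_rate", "momentum", "batch_size",
             "stages", "eval"}
_STAGE_KEYS = {"train_manifest", "val_manifest", "unlabeled_dir", "val_dir", "epochs",
               "learning_rate", "momentum", "batch_size", "seed", "online_augment",
               "max_val_images", "threshold"}
_EVAL_KEYS = {"stage", "manifest", "tta"}


def _validate_pipeline_schema(config: dict) -> None:
    """Reject unknown keys before any work starts."""
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
    for stage, opts in config.get("stages", {}).items():
        if stage not in STAGE_IDS:
            raise ConfigError(f"unknown stage {stage!r}; expected one of {STAGE_IDS}")
        bad = set(opts) - _STAGE_KEYS
        if bad:
            raise ConfigError(f"stage {stage!r} has unknown keys: {sorted(bad)}")
    bad = set(config.get("eval", {}) or {}) - _EVAL_KEYS
    if bad:
        raise ConfigError(f"eval section has unknown keys: {sorted(bad)}")


def _require(config: dict, stage: str, key: str):
    stages = config.get("stages", {})
    if stage not in stages:
        raise ConfigError(f"pipeline config missing stage {stage!r}")
    if key not in stages[stage]:
        raise ConfigError(f"stage {stage!r} is missing required key {key!r}")
    value = stages[stage][key]
    if isinstance(value, (str, os.PathLike)) and not Path(value).exists():
        raise ConfigError(f"stage {stage!r}: path for {key!r} does not exist: {value}")
    return value


def run_pipeline(config: dict, log=print) -> dict[str, StageCheckpoint]:
    """Run S -> D -> P -> G (chained) plus the independent Baseline.

    ``config`` carries a workdir, global training defaults, and per-stage
    dataset references: manifests for S/D/G/baseline; for P, a directory of
    unlabeled frames (pseudo-labeled with model D) and one of validation
    frames. See the pipeline YAML produced by the CLI for the schema.
    """
    _validate_pipeline_schema(config)
    workdir = Path(config.get("workdir", "."))
    ckpt_dir = workdir / "checkpoints"
    defaults = {
        "encoder": config.get("encoder", "tiny"),
        "learning_rate": config.get("learning_rate", 0.01),
        "momentum": config.get("momentum", 0.9),
        "batch_size": config.get("batch_size", 8),
        "seed": config.get("seed", 0),
    }

    # validate everything up front so failures name the stage
    for stage in ("S", "D", "G", "baseline"):
        _require(config, stage, "train_manifest")
        _require(config, stage, "val_manifest")
    _require(config, "P", "unlabeled_dir")
    _require(config, "P", "val_dir")

    def stage_cfg(stage: str, train, val, init, **extra) -> StageConfig:
        opts = config["stages"].get(stage, {})
        return StageConfig(
            stage_id=stage,
            train_manifest=train,
            val_manifest=val,
            init_from=init,
            epochs=int(opts.get("epochs", DEFAULT_EPOCHS[stage])),
            learning_rate=float(opts.get("learning_rate", defaults["learning_rate"])),
            momentum=float(opts.get("momentum", defaults["momentum"])),
            batch_size=int(opts.get("batch_size", defaults["batch_size"])),
            seed=int(opts.get("seed", defaults["seed"])),
            encoder=defaults["encoder"],
            online_augment=bool(opts.get("online_augment", extra.pop("online_augment", False))),
            max_val_images=opts.get("max_val_images"),
            out_dir=ckpt_dir,
        )

    checkpoints: dict[str, StageCheckpoint] = {}
    s_opts = config["stages"]

    log("[pipeline] stage S: training on synthesized data")
    checkpoints["S"] = train_stage(
        stage_cfg("S", s_opts["S"]["train_manifest"], s_opts["S"]["val_manifest"], None)
    )

    log("[pipeline] stage D: fine-tuning on rotation-expanded annotated frames")
    checkpoints["D"] = train_stage(
        stage_cfg(
            "D",
            s_opts["D"]["train_manifest"],
            s_opts["D"]["val_manifest"],
            checkpoints["S"].weights_path,
            online_augment=True,
        )
    )

    log("[pipeline] stage P: pseudo-labeling unlabeled frames with model D")
    from .framestore import extract_frames

    net_d, _ = load_checkpoint(checkpoints["D"].weights_path)
    unlabeled = extract_frames(s_opts["P"]["unlabeled_dir"])
    val_frames = extract_frames(s_opts["P"]["val_dir"])
    pseudo_dir = workdir / "pseudo"
    thr = float(s_opts["P"].get("threshold", 0.5))
    p_train = generate_pseudo_labels(net_d, unlabeled, pseudo_dir, threshold=thr, split="train")
    p_val = generate_pseudo_labels(net_d, val_frames, pseudo_dir, threshold=thr, split="val")
    checkpoints["P"] = train_stage(
        stage_cfg("P", p_train, p_val, checkpoints["D"].weights_path)
    )

    log("[pipeline] stage G: few-shot fine-tuning on annotated external frames")
    checkpoints["G"] = train_stage(
        stage_cfg(
            "G",
            s_opts["G"]["train_manifest"],
            s_opts["G"]["val_manifest"],
            checkpoints["P"].weights_path,
        )
    )

    log("[pipeline] baseline: training from scratch on the stage-G data")
    checkpoints["baseline"] = train_stage(
        stage_cfg(
            "baseline",
            s_opts["baseline"]["train_manifest"],
            s_opts["baseline"]["val_manifest"],
            None,
        )
    )
    return checkpoints
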