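"""End-to-end fixture study: the full staged pipeline on simulated data.

Assembles the whole workflow at desk scale from the procedural field
simulator: clip generation and partition, cutout banks from the single
annotated training frame, composite synthesis, the staged training runs
(S, D, P, G, baseline), and held-out evaluation on annotated test frames
with and without test-time augmentation.

The defaults mirror the study protocol scaled to fixture size: a 60-frame
clip and 4 background frames at 96x96, 300 synthesized training composites
(10:1 train:val, matching the 10,000/1,000 design), 10-100 pasted heads per
composite, SGD at learning rate 0.01 with batch size 8, and min-val-loss
model selection at every stage.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import fieldsim, framestore, imgio, metrics, synthesis
from .adapt import generate_pseudo_labels, merge_manifests, rotations_dataset, run_pipeline
from .cutouts import cut_fake_instances, extract_instances
from .manifest import DatasetManifest
from .model import UNetSegmenter
from .nn import load_checkpoint


@dataclass
class StudyConfig:
    """Problem sizes and schedule of the fixture study."""

    canvas: int = 96
    n_frames: int = 60
    fps: float = 10.0
    n_backgrounds: int = 4
    n_test: int = 10
    n_val_frames: int = 5
    n_train_images: int = 300
    n_val_images: int = 30
    n_range: tuple[int, int] = (10, 100)
    batch_size: int = 8
    learning_rate: float = 0.01
    epochs: dict = field(
        default_factory=lambda: {"S": 10, "D": 3, "P": 3, "G": 2, "baseline": 2}
    )
    max_val_images: int | None = 60
    encoder: str = "tiny"
    seed: int = 0


def _background_frames(cfg: StudyConfig, rng_base: int) -> list[framestore.Frame]:
    # background clips come from different fields: shift the palette so a
    # genuine appearance gap separates composites from the wheat clip
    spec = fieldsim.FieldSpec(
        canvas=(cfg.canvas, cfg.canvas), background_rgb=(0.36, 0.33, 0.20), seed=rng_base
    )
    return [
        framestore.Frame(index=i, image=fieldsim.make_background(spec, seed=rng_base + i).image,
                         clip_id=f"bg-{i}")
        for i in range(cfg.n_backgrounds)
    ]


def build_fixture_study(workdir: str | os.PathLike, cfg: StudyConfig) -> dict:
    """Generate all datasets and a pipeline config; returns the config dict.

    Layout under ``workdir``: synth_train/, synth_val/, rot_wt/, rot_wv/,
    unlabeled/, val_frames/, theta_train/, theta_val/, test/ (annotated
    held-out frames).
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    cv = (cfg.canvas, cfg.canvas)
    seed = cfg.seed

    field_spec = fieldsim.FieldSpec(canvas=cv, n_heads=6, seed=seed)
    clip = fieldsim.make_clip(
        field_spec, n_frames=cfg.n_frames, drift_px_per_frame=1, seed=seed, fps=cfg.fps
    )
    part = framestore.partition_frames(
        clip.frames,
        fps=cfg.fps,
        idx_t=0,
        idx_v=cfg.n_frames - 1,
        n_test=cfg.n_test,
        n_val=cfg.n_val_frames,
        seed=seed + 1,
    )

    # Step I: cutout banks from the one annotated frame w_t
    real = extract_instances(part.w_t.image, clip.instance_masks[0], source_id="wt")
    fake = cut_fake_instances(
        part.w_t.image,
        clip.masks[0],
        [c.footprint for c in real.cutouts],
        rng_seed=seed + 2,
        source_id="wt",
    )
    real_v = extract_instances(part.w_v.image, clip.instance_masks[-1], source_id="wv")
    fake_v = cut_fake_instances(
        part.w_v.image,
        clip.masks[-1],
        [c.footprint for c in real_v.cutouts],
        rng_seed=seed + 3,
        source_id="wv",
    )

    # Step II: synthesized training/validation composites
    bgs = _background_frames(cfg, rng_base=seed + 1000)
    synthesis.synthesize_dataset(
        bgs, real, fake, workdir / "synth_train", n_images=cfg.n_train_images,
        base_seed=seed + 10_000, n_range=cfg.n_range, stage="S", split="train",
    )
    synthesis.synthesize_dataset(
        bgs, real_v, fake_v, workdir / "synth_val", n_images=cfg.n_val_images,
        base_seed=seed + 50_000, n_range=cfg.n_range, stage="S", split="val",
    )

    # Domain adaptation step I: 360-degree rotation expansion of w_t / w_v
    rotations_dataset(part.w_t.image, clip.masks[0], workdir / "rot_wt",
                      online_augment=True, stage="D", split="train", source_id="wt")
    rotations_dataset(part.w_v.image, clip.masks[-1], workdir / "rot_wv",
                      online_augment=True, stage="D", split="val", source_id="wv")

    # unlabeled frames for pseudo-labeling + held-back validation frames
    framestore.write_frames(part.unlabeled, workdir / "unlabeled")
    framestore.write_frames(part.val_set, workdir / "val_frames")

    # Step III data: the two annotated clip frames plus one extra annotated
    # frame per split from a different simulated field (the external domain)
    ext_spec = fieldsim.FieldSpec(
        canvas=cv, n_heads=7, background_rgb=(0.27, 0.36, 0.24),
        head_rgb=(0.75, 0.72, 0.50), seed=seed + 7,
    )
    ext_t, ext_t_inst = fieldsim.make_field_frame(ext_spec, seed=seed + 8)
    ext_v, ext_v_inst = fieldsim.make_field_frame(ext_spec, seed=seed + 9)
    ext_t_mask = np.bitwise_or.reduce(np.stack(ext_t_inst), axis=0)
    ext_v_mask = np.bitwise_or.reduce(np.stack(ext_v_inst), axis=0)
    th_t_a = rotations_dataset(part.w_t.image, clip.masks[0], workdir / "theta_train",
                               stage="G", split="train", source_id="wt")
    th_t_b = rotations_dataset(ext_t.image, ext_t_mask, workdir / "theta_train",
                               stage="G", split="train", source_id="ext")
    merge_manifests([th_t_a, th_t_b], workdir / "theta_train" / "manifest.csv")
    th_v_a = rotations_dataset(part.w_v.image, clip.masks[-1], workdir / "theta_val",
                               stage="G", split="val", source_id="wv")
    th_v_b = rotations_dataset(ext_v.image, ext_v_mask, workdir / "theta_val",
                               stage="G", split="val", source_id="ext")
    merge_manifests([th_v_a, th_v_b], workdir / "theta_val" / "manifest.csv")

    # annotated internal test set
    test_dir = workdir / "test"
    (test_dir / "images").mkdir(parents=True, exist_ok=True)
    (test_dir / "masks").mkdir(parents=True, exist_ok=True)
    from .manifest import make_row

    rows = []
    for f in part.test_set:
        name = f"frame_{f.index:05d}.png"
        imgio.save_image(test_dir / "images" / name, f.image)
        imgio.save_mask(test_dir / "masks" / name, clip.masks[f.index])
        rows.append(make_row(id=f"test-{f.index:05d}", image_path=f"images/{name}",
                             mask_path=f"masks/{name}", split="test", stage="eval",
                             domain="internal", seed=f.index))
    DatasetManifest.from_rows(rows, root=test_dir).save()

    config = {
        "workdir": str(workdir),
        "encoder": cfg.encoder,
        "seed": seed,
        "learning_rate": cfg.learning_rate,
        "batch_size": cfg.batch_size,
        "stages": {
            "S": {
                "train_manifest": str(workdir / "synth_train" / "manifest.csv"),
                "val_manifest": str(workdir / "synth_val" / "manifest.csv"),
                "epochs": cfg.epochs["S"],
            },
            "D": {
                "train_manifest": str(workdir / "rot_wt" / "manifest_wt.csv"),
                "val_manifest": str(workdir / "rot_wv" / "manifest_wv.csv"),
                "epochs": cfg.epochs["D"],
                "online_augment": True,
                "max_val_images": cfg.max_val_images,
            },
            "P": {
                "unlabeled_dir": str(workdir / "unlabeled"),
                "val_dir": str(workdir / "val_frames"),
                "epochs": cfg.epochs["P"],
            },
            "G": {
                "train_manifest": str(workdir / "theta_train" / "manifest.csv"),
                "val_manifest": str(workdir / "theta_val" / "manifest.csv"),
                "epochs": cfg.epochs["G"],
                "max_val_images": cfg.max_val_images,
            },
            "baseline": {
                "train_manifest": str(workdir / "theta_train" / "manifest.csv"),
                "val_manifest": str(workdir / "theta_val" / "manifest.csv"),
                "epochs": cfg.epochs["baseline"],
                "max_val_images": cfg.max_val_images,
            },
        },
    }
    return config


def run_fixture_study(
    workdir: str | os.PathLike,
    cfg: StudyConfig | None = None,
    tta: bool = True,
    log=lambda msg: None,
) -> dict:
    """Build the fixture datasets, run all five stages, and evaluate them.

    Returns {"checkpoints": {stage: StageCheckpoint}, "scores": {stage:
    {"dice", "iou", "tta_dice", "tta_iou"}}} on the held-out annotated test
    frames.
    """
    cfg = cfg or StudyConfig()
    workdir = Path(workdir)
    config = build_fixture_study(workdir, cfg)
    checkpoints = run_pipeline(config, log=log)
    test_man = DatasetManifest.load(workdir / "test" / "manifest.csv")
    scores = {}
    for stage, ckpt in checkpoints.items():
        net, _ = load_checkpoint(ckpt.weights_path)
        _, summary = metrics.evaluate(net, test_man, tta=False)
        entry = {"dice": summary["dice"], "iou": summary["iou"], "n": summary["n_images"]}
        if tta:
            _, tta_summary = metrics.evaluate(net, test_man, tta=True, tta_seed=cfg.seed)
            entry["tta_dice"] = tta_summary["dice"]
            entry["tta_iou"] = tta_summary["iou"]
        scores[stage] = entry
        log(f"[study] {stage}: dice={entry['dice']:.4f} iou={entry['iou']:.4f}")
    return {"checkpoints": checkpoints, "scores": scores, "config": config}


def compare_s_vs_d(seed: int, canvas: int = 48, n_train: int = 48) -> tuple[float, float]:
    """Small-scale S-vs-D contrast: held-out Dice before and after Step I.

    Trains model S on composites only, fine-tunes it on the 360 rotations of
    the annotated frame (model D), and scores both on annotated held-out
    clip frames. In-memory and small so that repeating it over seeds is
    cheap.
    """
    cv = (canvas, canvas)
    spec = fieldsim.FieldSpec(canvas=cv, n_heads=4, minor_axis=(5, 7), major_axis=(8, 11),
                              seed=seed)
    clip = fieldsim.make_clip(spec, n_frames=20, drift_px_per_frame=1, seed=seed, fps=4)
    part = framestore.partition_frames(
        clip.frames, fps=4, idx_t=0, idx_v=19, n_test=6, n_val=0, seed=seed + 1
    )
    real = extract_instances(part.w_t.image, clip.instance_masks[0])
    fake = cut_fake_instances(
        part.w_t.image, clip.masks[0], [c.footprint for c in real.cutouts], rng_seed=seed + 2
    )
    bg_spec = fieldsim.FieldSpec(canvas=cv, background_rgb=(0.36, 0.33, 0.20), seed=seed)
    bgs = [
        framestore.Frame(index=i, image=fieldsim.make_background(bg_spec, seed=seed + 900 + i).image,
                         clip_id=f"bg-{i}")
        for i in range(3)
    ]
    n_rng = (5, 25)
    Xt, yt, Xv, yv = [], [], [], []
    for i in range(n_train):
        s = synthesis.sample_for_seed(bgs, real, fake, seed=seed * 100_000 + i, n_range=n_rng)
        Xt.append(s.image), yt.append(s.mask)
    for i in range(8):
        s = synthesis.sample_for_seed(bgs, real, fake, seed=seed * 100_000 + 90_000 + i, n_range=n_rng)
        Xv.append(s.image), yv.append(s.mask)

    est_s = UNetSegmenter(encoder="tiny", epochs=4, batch_size=8, seed=seed)
    est_s.fit(Xt, yt, Xv, yv)

    import tempfile

    with tempfile.TemporaryDirectory() as tmp:
        rot_t = rotations_dataset(part.w_t.image, clip.masks[0], Path(tmp) / "t", source_id="wt")
        rot_v = rotations_dataset(part.w_v.image, clip.masks[-1], Path(tmp) / "v", source_id="wv")
        from .adapt import load_dataset

        Xr, yr = load_dataset(rot_t)
        Xrv, yrv = load_dataset(rot_v, max_images=24, seed=seed)
    est_d = UNetSegmenter(encoder="tiny", epochs=1, batch_size=8, seed=seed, online_augment=True)
    est_d.fit(Xr, yr, Xrv, yrv, init_state=est_s.net_.state_dict())

    test_imgs = [f.image for f in part.test_set]
    test_masks = [clip.masks[f.index] for f in part.test_set]
    return est_s.score(test_imgs, test_masks), est_d.score(test_imgs, test_masks)
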