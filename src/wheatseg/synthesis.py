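"""Cut-and-paste synthesis of computationally annotated images.

A composite is built on a background frame by overlaying fake head cutouts
first, then real head cutouts (painter's order: later pastes occlude
earlier ones). Each cutout is geometrically augmented — flips, rotation,
resizing, elastic deformation — before placement, with the identical map
applied to patch and footprint. The ground-truth mask is the union of the
placed real footprints; fakes contribute no mask pixels. Color augmentation
is applied to the finished composite only, never to the mask, so the label
remains computationally inferable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import transform as sktransform

from . import imgio
from .cutouts import Cutout, CutoutSet, tight_bbox
from .errors import AugmentationError, InputError
from .framestore import Frame
from .manifest import DatasetManifest, make_row


@dataclass
class AugmentParams:
    """Geometric augmentation ranges for cutouts.

    rotation is in degrees; scale is a multiplicative factor range; elastic
    deformation displaces pixels by a Gaussian-smoothed random field with
    amplitude ``elastic_alpha`` (pixels) and smoothness ``elastic_sigma``.
    """

    hflip: bool = True
    vflip: bool = True
    rotation: tuple[float, float] = (-180.0, 180.0)
    scale: tuple[float, float] = (0.5, 1.5)
    elastic_alpha: float = 1.5
    elastic_sigma: float = 3.0
    elastic_prob: float = 0.3

    @classmethod
    def identity(cls) -> "AugmentParams":
        return cls(
            hflip=False,
            vflip=False,
            rotation=(0.0, 0.0),
            scale=(1.0, 1.0),
            elastic_alpha=0.0,
            elastic_prob=0.0,
        )

    def is_identity(self) -> bool:
        return (
            not self.hflip
            and not self.vflip
            and self.rotation == (0.0, 0.0)
            and self.scale == (1.0, 1.0)
            and (self.elastic_alpha == 0.0 or self.elastic_prob == 0.0)
        )


@dataclass
class Transform:
    """One sampled geometric map (shared by patch and footprint)."""

    hflip: bool = False
    vflip: bool = False
    angle: float = 0.0
    scale: float = 1.0
    elastic_seed: int | None = None
    elastic_alpha: float = 0.0
    elastic_sigma: float = 3.0

    def is_identity(self) -> bool:
        return (
            not self.hflip
            and not self.vflip
            and self.angle == 0.0
            and self.scale == 1.0
            and self.elastic_seed is None
        )


def _sample_transform(rng: np.random.Generator, params: AugmentParams) -> Transform:
    elastic = params.elastic_alpha > 0 and rng.random() < params.elastic_prob
    return Transform(
        hflip=bool(params.hflip and rng.random() < 0.5),
        vflip=bool(params.vflip and rng.random() < 0.5),
        angle=float(rng.uniform(*params.rotation)),
        scale=float(rng.uniform(*params.scale)),
        elastic_seed=int(rng.integers(2**31)) if elastic else None,
        elastic_alpha=params.elastic_alpha if elastic else 0.0,
        elastic_sigma=params.elastic_sigma,
    )


def _apply_transform(
    patch: np.ndarray, footprint: np.ndarray, t: Transform
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the same geometric map to patch (bilinear) and footprint.

    The footprint is interpolated as a float field and re-binarized at 0.5.
    """
    img = patch.astype(np.float64)
    fp = footprint.astype(np.float64)
    if t.scale != 1.0:
        img = sktransform.rescale(
            img, t.scale, channel_axis=2, order=1, anti_aliasing=False, mode="edge"
        )
        fp = sktransform.rescale(fp, t.scale, order=1, anti_aliasing=False, mode="constant")
    if t.angle != 0.0:
        img = sktransform.rotate(img, t.angle, resize=True, order=1, mode="edge")
        fp = sktransform.rotate(fp, t.angle, resize=True, order=1, mode="constant", cval=0.0)
    if t.hflip:
        img, fp = img[:, ::-1], fp[:, ::-1]
    if t.vflip:
        img, fp = img[::-1], fp[::-1]
    if t.elastic_seed is not None and t.elastic_alpha > 0:
        erng = np.random.default_rng(t.elastic_seed)
        h, w = fp.shape
        dr = ndimage.gaussian_filter(erng.uniform(-1, 1, (h, w)), t.elastic_sigma) * t.elastic_alpha
        dc = ndimage.gaussian_filter(erng.uniform(-1, 1, (h, w)), t.elastic_sigma) * t.elastic_alpha
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        coords = np.stack([rr + dr, cc + dc])
        fp = ndimage.map_coordinates(fp, coords, order=1, mode="constant")
        img = np.stack(
            [ndimage.map_coordinates(img[..., k], coords, order=1, mode="nearest") for k in range(3)],
            axis=-1,
        )
    fp_bin = (fp >= 0.5).astype(np.uint8)
    if not fp_bin.any():
        return img.astype(np.float32), fp_bin
    # crop back to the tight box of the transformed footprint
    r0, c0, r1, c1 = tight_bbox(fp_bin)
    return (
        np.clip(img[r0:r1, c0:c1], 0, 1).astype(np.float32),
        fp_bin[r0:r1, c0:c1],
    )


def _augment_with_record(
    cutout: Cutout,
    rng_seed: int,
    params: AugmentParams,
    max_retries: int = 10,
) -> tuple[Cutout, "Transform"]:
    """Augment a cutout and return the sampled transform alongside it."""
    if params.is_identity():
        copy = replace(cutout, patch=cutout.patch.copy(), footprint=cutout.footprint.copy())
        return copy, Transform()
    rng = np.random.default_rng(rng_seed)
    for _ in range(max_retries):
        t = _sample_transform(rng, params)
        patch, fp = _apply_transform(cutout.patch, cutout.footprint, t)
        if fp.any():
            h, w = fp.shape
            return (
                Cutout(
                    patch=patch,
                    footprint=fp,
                    bbox=(0, 0, h, w),
                    kind=cutout.kind,
                    source_id=cutout.source_id,
                    cutout_id=cutout.cutout_id,
                ),
                t,
            )
    raise AugmentationError(
        f"augmentation emptied footprint of {cutout.cutout_id!r} in {max_retries} retries"
    )


def augment_cutout(
    cutout: Cutout,
    rng_seed: int,
    params: AugmentParams | None = None,
    max_retries: int = 10,
) -> Cutout:
    """Geometrically augment a cutout, resampling if the footprint empties."""
    params = params if params is not None else AugmentParams()
    aug, _ = _augment_with_record(cutout, rng_seed, params, max_retries)
    return aug


@dataclass
class Placement:
    """One paste operation, recorded so the mask can be re-rasterized."""

    cutout_id: str
    kind: str
    center: tuple[int, int]
    transform: Transform
    footprint: np.ndarray = field(repr=False, default=None)  # transformed, pre-clip
    top_left: tuple[int, int] = (0, 0)  # canvas coords of footprint[0,0]; may be negative


@dataclass
class SyntheticSample:
    """A composite image, its exact mask, and the placement log behind it."""

    image: np.ndarray
    mask: np.ndarray
    placements: list[Placement]
    background_id: str
    seed: int


def color_augment(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Photometric jitter: brightness/contrast, hue/saturation, blur, noise."""
    img = image.astype(np.float32)
    img = (img - img.mean()) * rng.uniform(0.8, 1.2) + img.mean() + rng.uniform(-0.08, 0.08)
    img = np.clip(img, 0, 1)
    hsv = skcolor.rgb2hsv(img)
    hsv[..., 0] = (hsv[..., 0] + rng.uniform(-0.03, 0.03)) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * rng.uniform(0.8, 1.2), 0, 1)
    img = skcolor.hsv2rgb(hsv).astype(np.float32)
    if rng.random() < 0.3:
        img = ndimage.gaussian_filter(img, sigma=(rng.uniform(0.4, 1.0),) * 2 + (0,))
    if rng.random() < 0.3:
        img = img + rng.normal(0, 0.02, img.shape)
    return np.clip(img, 0, 1).astype(np.float32)


def _paste(canvas: np.ndarray, patch: np.ndarray, fp: np.ndarray, center: tuple[int, int]):
    """Alpha-overlay ``patch`` (alpha = footprint) at ``center``, clipping at borders.

    Returns the clipped canvas-region slices and the clipped footprint, or
    None when the footprint falls fully outside the canvas.
    """
    H, W = canvas.shape[:2]
    h, w = fp.shape
    r0 = center[0] - h // 2
    c0 = center[1] - w // 2
    rr0, cc0 = max(r0, 0), max(c0, 0)
    rr1, cc1 = min(r0 + h, H), min(c0 + w, W)
    if rr0 >= rr1 or cc0 >= cc1:
        return None
    fp_clip = fp[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0]
    patch_clip = patch[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0]
    sel = fp_clip > 0
    canvas[rr0:rr1, cc0:cc1][sel] = patch_clip[sel]
    return (rr0, rr1, cc0, cc1), fp_clip, (r0, c0)


def compose(
    background: Frame,
    real_bank: CutoutSet,
    fake_bank: CutoutSet,
    rng_seed: int,
    n_range: tuple[int, int] = (10, 100),
    color_aug: bool = True,
    aug_params: AugmentParams | None = None,
) -> SyntheticSample:
    """Build one composite: fakes first, then reals; mask from reals only.

    The number of fake and of real heads are independent uniform draws from
    ``n_range`` (inclusive); cutouts are sampled with replacement. Placements
    extending past the canvas are clipped, not rejected.
    """
    rng = np.random.default_rng(rng_seed)
    low, high = n_range
    n_fake = int(rng.integers(low, high + 1))
    n_real = int(rng.integers(low, high + 1))
    if n_fake > 0 and len(fake_bank) == 0:
        raise InputError("fake bank is empty but n_fake > 0")
    if n_real > 0 and len(real_bank) == 0:
        raise InputError("real bank is empty but n_real > 0")

    canvas = background.image.astype(np.float32).copy()
    H, W = canvas.shape[:2]
    mask = np.zeros((H, W), dtype=np.uint8)
    placements: list[Placement] = []

    for kind, bank, count in (("fake", fake_bank, n_fake), ("real", real_bank, n_real)):
        for _ in range(count):
            src = bank[int(rng.integers(len(bank)))]
            aug_seed = int(rng.integers(2**31))
            params = aug_params if aug_params is not None else AugmentParams()
            aug, t = _augment_with_record(src, aug_seed, params)
            center = (int(rng.integers(0, H)), int(rng.integers(0, W)))
            pasted = _paste(canvas, aug.patch, aug.footprint, center)
            if pasted is not None and kind == "real":
                (rr0, rr1, cc0, cc1), fp_clip, _ = pasted
                mask[rr0:rr1, cc0:cc1] |= fp_clip
            top_left = (center[0] - aug.footprint.shape[0] // 2, center[1] - aug.footprint.shape[1] // 2)
            placements.append(
                Placement(
                    cutout_id=src.cutout_id,
                    kind=kind,
                    center=center,
                    transform=t,
                    footprint=aug.footprint,
                    top_left=top_left,
                )
            )
    if color_aug:
        canvas = color_augment(canvas, rng)
    return SyntheticSample(
        image=canvas,
        mask=mask,
        placements=placements,
        background_id=background.clip_id,
        seed=rng_seed,
    )


def sample_for_seed(
    backgrounds: list[Frame],
    real_bank: CutoutSet,
    fake_bank: CutoutSet,
    seed: int,
    n_range: tuple[int, int] = (10, 100),
    color_aug: bool = True,
    aug_params: AugmentParams | None = None,
) -> SyntheticSample:
    """Deterministically derive (background choice, composite) from one seed."""
    rng = np.random.default_rng(seed)
    bg = backgrounds[int(rng.integers(len(backgrounds)))]
    sub_seed = int(rng.integers(2**31))
    sample = compose(bg, real_bank, fake_bank, sub_seed, n_range, color_aug, aug_params)
    return replace(sample, seed=seed)


def synthesize_dataset(
    background_frames: list[Frame],
    real_bank: CutoutSet,
    fake_bank: CutoutSet,
    out_dir: str | os.PathLike,
    n_images: int = 10000,
    base_seed: int = 0,
    n_range: tuple[int, int] = (10, 100),
    color_aug: bool = True,
    aug_params: AugmentParams | None = None,
    split: str = "train",
    stage: str = "S",
) -> DatasetManifest:
    """Write ``n_images`` composites (image/mask PNG pairs) plus a manifest.

    Per-image seed is ``base_seed + index``, so any single sample can be
    regenerated without re-running the whole dataset.
    """
    if n_images < 0:
        raise InputError("n_images must be >= 0")
    if n_images > 0 and not background_frames:
        raise InputError("at least one background frame is required")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_images):
        seed = base_seed + i
        sample = sample_for_seed(
            background_frames, real_bank, fake_bank, seed, n_range, color_aug, aug_params
        )
        name = f"{stage.lower()}_{i:05d}.png"
        imgio.save_image(out / "images" / name, sample.image)
        imgio.save_mask(out / "masks" / name, sample.mask)
        rows.append(
            make_row(
                id=f"{stage}-{i:05d}",
                image_path=f"images/{name}",
                mask_path=f"masks/{name}",
                split=split,
                stage=stage,
                domain="synthetic",
                seed=seed,
            )
        )
    man = DatasetManifest.from_rows(rows, root=out)
    man.save()
    return man
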