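"""Procedural field-scene generator with exact ground-truth masks.

Emulates the raw inputs of the study design at desk scale: textured
background frames with no wheat, single wheat-field frames whose head
positions (and therefore masks) are known exactly, and temporally coherent
clips obtained by drifting a viewing window across a larger latent scene.

Heads are drawn as textured ellipses with a spikelet-like stripe pattern and
a few awn strokes; awns are painted on the image but excluded from the mask,
mirroring the field annotation convention that awns are not part of the
head region. Because masks are produced by the same rasterization that
paints the heads, fixture ground truth carries zero annotation noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line
from skimage.transform import resize

from .errors import CapacityError
from .framestore import Frame


@dataclass
class FieldSpec:
    """Parameters of the simulated field scene.

    Axis ranges are full ellipse axis lengths in pixels. The background is a
    smoothly varying two-tone field plus fine speckle noise around
    ``background_rgb``.
    """

    canvas: tuple[int, int] = (96, 96)
    n_heads: int = 6
    minor_axis: tuple[int, int] = (6, 9)
    major_axis: tuple[int, int] = (9, 14)
    stripe_freq: float = 1.6
    awn_count: tuple[int, int] = (2, 4)
    background_rgb: tuple[float, float, float] = (0.30, 0.38, 0.18)
    background_noise: float = 0.05
    head_rgb: tuple[float, float, float] = (0.80, 0.70, 0.42)
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.canvas
        if self.major_axis[1] >= min(h, w):
            raise CapacityError("head axes do not fit in canvas")
        if self.n_heads < 0:
            raise ValueError("n_heads must be >= 0")


def make_background(spec: FieldSpec, seed: int) -> Frame:
    """A textured head-free frame; deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    h, w = spec.canvas
    image = _paint_background(spec, rng, (h, w))
    return Frame(index=0, image=image, clip_id=f"background-{seed}")


def _paint_background(spec: FieldSpec, rng: np.random.Generator, shape) -> np.ndarray:
    h, w = shape
    base = np.asarray(spec.background_rgb, dtype=np.float32)
    # low-frequency tonal variation: coarse noise upsampled to the canvas
    coarse = rng.normal(0.0, 1.0, size=(max(h // 12, 2), max(w // 12, 2), 3))
    lowfreq = resize(coarse, (h, w, 3), order=1, anti_aliasing=False)
    speckle = rng.normal(0.0, 1.0, size=(h, w, 3))
    image = base + 0.35 * spec.background_noise * lowfreq + spec.background_noise * speckle
    return np.clip(image, 0.0, 1.0).astype(np.float32)


def _draw_head(
    image: np.ndarray,
    spec: FieldSpec,
    rng: np.random.Generator,
    center: tuple[int, int],
    axes: tuple[float, float],
    angle: float,
) -> np.ndarray:
    """Paint one head at ``center``; return its exact binary mask."""
    h, w = image.shape[:2]
    rr, cc = draw_ellipse(
        center[0], center[1], axes[0] / 2.0, axes[1] / 2.0, shape=(h, w), rotation=angle
    )
    mask = np.zeros((h, w), dtype=np.uint8)
    mask[rr, cc] = 1
    head_rgb = np.asarray(spec.head_rgb, dtype=np.float32)
    # spikelet stripes: intensity modulation along the major axis
    u = (rr - center[0]) * np.sin(angle) + (cc - center[1]) * np.cos(angle)
    stripes = 0.12 * np.sin(spec.stripe_freq * u * np.pi)
    tint = rng.normal(0.0, 0.03, size=3)
    colors = np.clip(head_rgb + tint + stripes[:, None], 0.0, 1.0)
    image[rr, cc] = colors.astype(np.float32)
    # awns: thin strokes from the head tip, painted but NOT in the mask
    n_awns = int(rng.integers(spec.awn_count[0], spec.awn_count[1] + 1))
    tip = np.array(
        [center[0] - (axes[1] / 2.0) * np.sin(angle), center[1] + (axes[1] / 2.0) * np.cos(angle)]
    )
    for _ in range(n_awns):
        theta = angle + rng.uniform(-0.5, 0.5)
        length = rng.uniform(0.4, 0.9) * axes[1]
        end = tip + length * np.array([-np.sin(theta), np.cos(theta)])
        r0, c0 = int(round(tip[0])), int(round(tip[1]))
        r1 = int(np.clip(round(end[0]), 0, h - 1))
        c1 = int(np.clip(round(end[1]), 0, w - 1))
        if 0 <= r0 < h and 0 <= c0 < w:
            lr, lc = draw_line(r0, c0, r1, c1)
            keep = mask[lr, lc] == 0
            image[lr[keep], lc[keep]] = np.clip(head_rgb * 0.85, 0, 1)
    return mask


def _place_heads(
    image: np.ndarray,
    spec: FieldSpec,
    rng: np.random.Generator,
    n_heads: int,
    max_attempts: int = 200,
) -> list[np.ndarray]:
    h, w = image.shape[:2]
    occupied = np.zeros((h, w), dtype=bool)
    masks: list[np.ndarray] = []
    margin = spec.major_axis[1] // 2 + 1
    for k in range(n_heads):
        placed = False
        for _ in range(max_attempts):
            center = (
                int(rng.integers(margin, h - margin)),
                int(rng.integers(margin, w - margin)),
            )
            axes = (
                rng.uniform(*spec.minor_axis),
                rng.uniform(*spec.major_axis),
            )
            angle = rng.uniform(-np.pi, np.pi)
            rr, cc = draw_ellipse(
                center[0], center[1], axes[0] / 2.0, axes[1] / 2.0, shape=(h, w), rotation=angle
            )
            if not spec.allow_overlap and occupied[rr, cc].any():
                continue
            mask = _draw_head(image, spec, rng, center, axes, angle)
            occupied |= mask.astype(bool)
            masks.append(mask)
            placed = True
            break
        if not placed:
            raise CapacityError(
                f"could not place head {k + 1}/{n_heads} without overlap "
                f"after {max_attempts} attempts"
            )
    return masks


def make_field_frame(spec: FieldSpec, seed: int) -> tuple[Frame, list[np.ndarray]]:
    """One wheat-field frame plus per-head instance masks (exact)."""
    rng = np.random.default_rng(seed)
    h, w = spec.canvas
    image = _paint_background(spec, rng, (h, w))
    masks = _place_heads(image, spec, rng, spec.n_heads)
    frame = Frame(index=0, image=image, clip_id=f"field-{seed}")
    return frame, masks


@dataclass
class ClipData:
    """A temporally coherent frame sequence with exact per-frame masks."""

    frames: list[Frame]
    masks: list[np.ndarray]  # per-frame union masks {0,1}
    instance_masks: list[list[np.ndarray]] = field(default_factory=list)
    fps: float = 30.0


def make_clip(
    spec: FieldSpec,
    n_frames: int,
    drift_px_per_frame: int = 1,
    seed: int = 0,
    fps: float = 30.0,
) -> ClipData:
    """Frames as successive windows into one larger latent field scene.

    The window drifts horizontally by ``drift_px_per_frame`` pixels per
    frame, so frame t's mask is frame 0's mask translated accordingly
    (clipped at the latent scene boundary).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    h, w = spec.canvas
    latent_w = w + drift_px_per_frame * max(n_frames - 1, 0)
    density = spec.n_heads / (h * w)
    latent_n = max(spec.n_heads, int(round(density * h * latent_w)))
    latent_spec = replace(spec, canvas=(h, latent_w), n_heads=latent_n)
    image = _paint_background(latent_spec, rng, (h, latent_w))
    inst = _place_heads(image, latent_spec, rng, latent_n)
    union = np.zeros((h, latent_w), dtype=np.uint8)
    for m in inst:
        union |= m

    frames, masks, inst_per_frame = [], [], []
    clip_id = f"clip-{seed}"
    for t in range(n_frames):
        c0 = t * drift_px_per_frame
        frames.append(Frame(index=t, image=image[:, c0 : c0 + w].copy(), clip_id=clip_id))
        masks.append(union[:, c0 : c0 + w].copy())
        window_inst = []
        for m in inst:
            crop = m[:, c0 : c0 + w]
            if crop.any():
                window_inst.append(crop.copy())
        inst_per_frame.append(window_inst)
    return ClipData(frames=frames, masks=masks, instance_masks=inst_per_frame, fps=fps)
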