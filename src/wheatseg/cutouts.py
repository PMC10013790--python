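"""Head cutout banks: real instances and cookie-cutter fakes.

Real cutouts are the annotated head instances of a frame, cropped to their
tight bounding box. Fake cutouts reuse those footprints as cookie cutters to
stamp out head-free regions of the same frame: patches with the exact shape
of a head but containing only background. Composites built later place fakes
first so a model cannot separate heads from background by paste-boundary
artifacts alone.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import imgio
from .errors import InputError, PlacementError


@dataclass
class Cutout:
    """An image patch plus its binary footprint and provenance."""

    patch: np.ndarray  # h x w x 3 float in [0,1]
    footprint: np.ndarray  # h x w uint8 {0,1}
    bbox: tuple[int, int, int, int]  # (r0, c0, r1, c1), half-open, source coords
    kind: str  # "real" | "fake"
    source_id: str = ""
    cutout_id: str = ""

    def __post_init__(self) -> None:
        if self.patch.shape[:2] != self.footprint.shape:
            raise InputError("patch and footprint shapes differ")
        if not self.footprint.any():
            raise InputError("cutout footprint is empty")
        if self.kind not in ("real", "fake"):
            raise InputError(f"kind must be real|fake, got {self.kind!r}")


@dataclass
class CutoutSet:
    """A homogeneous bank of real or fake cutouts."""

    cutouts: list[Cutout]
    kind: str
    source_id: str = ""

    def __post_init__(self) -> None:
        for c in self.cutouts:
            if c.kind != self.kind:
                raise InputError("CutoutSet must be homogeneous in kind")

    def __len__(self) -> int:
        return len(self.cutouts)

    def __getitem__(self, i: int) -> Cutout:
        return self.cutouts[i]


def tight_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Half-open tight bounding box (r0, c0, r1, c1) of a non-empty mask."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1


def instances_from_semantic(mask: np.ndarray) -> list[np.ndarray]:
    """Split a semantic mask into instances via 8-connected components."""
    labeled, n = ndimage.label(mask > 0, structure=np.ones((3, 3), dtype=int))
    return [(labeled == k).astype(np.uint8) for k in range(1, n + 1)]


def extract_instances(
    image: np.ndarray, instance_masks: list[np.ndarray], source_id: str = ""
) -> CutoutSet:
    """One real cutout per instance mask, cropped to the tight bbox.

    Patches keep the background pixels outside the footprint; compositing
    later uses the footprint as the alpha channel.
    """
    cutouts = []
    for i, m in enumerate(instance_masks):
        if m.shape != image.shape[:2]:
            raise InputError(f"instance mask {i} shape {m.shape} != image {image.shape[:2]}")
        if not m.any():
            raise InputError(f"instance mask {i} is empty")
        r0, c0, r1, c1 = tight_bbox(m)
        cutouts.append(
            Cutout(
                patch=image[r0:r1, c0:c1].copy(),
                footprint=(m[r0:r1, c0:c1] > 0).astype(np.uint8),
                bbox=(r0, c0, r1, c1),
                kind="real",
                source_id=source_id,
                cutout_id=f"real-{i:04d}",
            )
        )
    return CutoutSet(cutouts=cutouts, kind="real", source_id=source_id)


def cut_fake_instances(
    image: np.ndarray,
    head_union: np.ndarray,
    templates: list[np.ndarray],
    rng_seed: int = 0,
    max_attempts: int = 1000,
    source_id: str = "",
) -> CutoutSet:
    """Cookie-cutter fake cutouts from head-free regions of ``image``.

    Each template footprint is translated to a seeded uniform-random
    position, rejected while it intersects ``head_union``, and accepted as a
    fake cutout once it lies entirely on head-free pixels.
    """
    if head_union.shape != image.shape[:2]:
        raise InputError("head_union shape must match image")
    H, W = head_union.shape
    head = head_union > 0
    rng = np.random.default_rng(rng_seed)
    cutouts = []
    for i, tmpl in enumerate(templates):
        t = (tmpl > 0).astype(np.uint8)
        if not t.any():
            raise InputError(f"template {i} is empty")
        th, tw = t.shape
        if th > H or tw > W:
            raise InputError(f"template {i} ({th}x{tw}) does not fit inside image ({H}x{W})")
        placed = False
        for _ in range(max_attempts):
            r0 = int(rng.integers(0, H - th + 1))
            c0 = int(rng.integers(0, W - tw + 1))
            if not (head[r0 : r0 + th, c0 : c0 + tw] & (t > 0)).any():
                cutouts.append(
                    Cutout(
                        patch=image[r0 : r0 + th, c0 : c0 + tw].copy(),
                        footprint=t.copy(),
                        bbox=(r0, c0, r0 + th, c0 + tw),
                        kind="fake",
                        source_id=source_id,
                        cutout_id=f"fake-{i:04d}",
                    )
                )
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"no head-free placement for template {i} within {max_attempts} attempts"
            )
    return CutoutSet(cutouts=cutouts, kind="fake", source_id=source_id)


def save_bank(bank: CutoutSet, out_dir: str | os.PathLike) -> Path:
    """Persist a bank as paired PNGs plus a CSV index."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, c in enumerate(bank.cutouts):
        cid = c.cutout_id or f"{bank.kind}-{i:04d}"
        imgio.save_image(out / f"{cid}_patch.png", c.patch)
        imgio.save_mask(out / f"{cid}_footprint.png", c.footprint)
        rows.append(
            {
                "id": cid,
                "kind": c.kind,
                "r0": c.bbox[0],
                "c0": c.bbox[1],
                "r1": c.bbox[2],
                "c1": c.bbox[3],
                "source_id": c.source_id,
            }
        )
    index = out / "index.csv"
    pd.DataFrame(rows).to_csv(index, index=False)
    return index


def load_bank(bank_dir: str | os.PathLike) -> CutoutSet:
    bank_dir = Path(bank_dir)
    index = bank_dir / "index.csv"
    if not index.exists():
        raise InputError(f"no cutout index at {index}")
    df = pd.read_csv(index)
    if df.empty:
        raise InputError(f"cutout bank at {bank_dir} is empty")
    cutouts = []
    for _, row in df.iterrows():
        cutouts.append(
            Cutout(
                patch=imgio.load_image(bank_dir / f"{row['id']}_patch.png"),
                footprint=imgio.load_mask(bank_dir / f"{row['id']}_footprint.png"),
                bbox=(int(row["r0"]), int(row["c0"]), int(row["r1"]), int(row["c1"])),
                kind=str(row["kind"]),
                source_id=str(row["source_id"]) if not pd.isna(row["source_id"]) else "",
                cutout_id=str(row["id"]),
            )
        )
    return CutoutSet(cutouts=cutouts, kind=cutouts[0].kind, source_id=cutouts[0].source_id)
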