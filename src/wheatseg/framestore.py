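"""Frame extraction and the five-way clip partition.

A wheat-field clip is split into: one frame for synthesizing training data
(w_t), one for synthesizing validation data (w_v), an annotated test set,
a small validation set, and the remaining unlabeled frames used for
pseudo-labeling. Test and validation frames must be temporally distant from
w_t and w_v — more than one second away in clip time — so that evaluation
frames are not near-duplicates of the two annotated frames.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import imgio
from .errors import CapacityError, InputError


@dataclass
class Frame:
    """One video frame: an RGB array in [0,1] plus its clip-time index."""

    index: int
    image: np.ndarray
    clip_id: str = ""

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("frame index must be >= 0")
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise InputError(f"frame image must be HxWx3, got {self.image.shape}")


@dataclass
class FramePartition:
    """Five-way split of a clip's frames (disjoint by index)."""

    w_t: Frame
    w_v: Frame
    test_set: list[Frame]
    val_set: list[Frame]
    unlabeled: list[Frame]
    fps: float

    def __post_init__(self) -> None:
        groups = {
            "wt": [self.w_t.index],
            "wv": [self.w_v.index],
            "test": [f.index for f in self.test_set],
            "val": [f.index for f in self.val_set],
            "unlabeled": [f.index for f in self.unlabeled],
        }
        seen: set[int] = set()
        for name, idxs in groups.items():
            overlap = seen.intersection(idxs)
            if overlap:
                raise InputError(f"partition parts overlap at indices {sorted(overlap)} ({name})")
            seen.update(idxs)

    def split_of(self, index: int) -> str:
        if index == self.w_t.index:
            return "wt"
        if index == self.w_v.index:
            return "wv"
        for name, frames in (
            ("test", self.test_set),
            ("val", self.val_set),
            ("unlabeled", self.unlabeled),
        ):
            if any(f.index == index for f in frames):
                return name
        raise KeyError(index)


def extract_frames(source: str | os.PathLike, stride: int = 1) -> list[Frame]:
    """Read frames from a clip file or a directory of image frames.

    Indices are original frame numbers (before striding): a 10-frame source
    at stride 2 yields frames 0, 2, 4, 6, 8.
    """
    if stride < 1:
        raise ValueError("stride must be a positive integer")
    source = Path(source)
    if source.is_dir():
        paths = imgio.list_frames(source)
        if not paths:
            raise InputError(f"no image frames found in directory {source}")
        images = [imgio.load_image(p) for p in paths]
    elif source.is_file():
        import imageio.v3 as iio

        try:
            images = [imgio.to_float(im) for im in iio.imiter(source)]
        except Exception as exc:  # codec/plugin failures vary by backend
            raise InputError(f"cannot decode clip {source}: {exc}") from exc
        if not images:
            raise InputError(f"clip {source} decoded to zero frames")
    else:
        raise InputError(f"source does not exist: {source}")
    clip_id = source.stem if source.name else str(source)
    return [
        Frame(index=i, image=images[i], clip_id=clip_id)
        for i in range(0, len(images), stride)
    ]


def partition_frames(
    frames: list[Frame],
    fps: float,
    idx_t: int,
    idx_v: int,
    n_test: int,
    n_val: int,
    seed: int = 0,
) -> FramePartition:
    """Split frames into {w_t, w_v, test, val, unlabeled}.

    Test and val frames are sampled uniformly without replacement (seeded)
    from frames whose index distance to both idx_t and idx_v exceeds
    round(fps) — i.e. frames more than one second away in clip time. w_t and
    w_v never appear in any other part; leftover frames become the unlabeled
    set.
    """
    if idx_t == idx_v:
        raise InputError("idx_t and idx_v must differ")
    by_index = {f.index: f for f in frames}
    if idx_t not in by_index or idx_v not in by_index:
        raise InputError("idx_t and idx_v must both be present in frames")
    window = int(round(fps))
    eligible = sorted(
        i for i in by_index if abs(i - idx_t) > window and abs(i - idx_v) > window
    )
    if n_test + n_val > len(eligible):
        raise CapacityError(
            f"requested {n_test} test + {n_val} val frames but only "
            f"{len(eligible)} frames lie outside the one-second windows"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(eligible), size=n_test + n_val, replace=False)
    test_idx = sorted(eligible[i] for i in picked[:n_test])
    val_idx = sorted(eligible[i] for i in picked[n_test:])
    taken = {idx_t, idx_v, *test_idx, *val_idx}
    unlabeled_idx = sorted(i for i in by_index if i not in taken)
    return FramePartition(
        w_t=by_index[idx_t],
        w_v=by_index[idx_v],
        test_set=[by_index[i] for i in test_idx],
        val_set=[by_index[i] for i in val_idx],
        unlabeled=[by_index[i] for i in unlabeled_idx],
        fps=fps,
    )


def write_frames(frames: list[Frame], out_dir: str | os.PathLike) -> list[Path]:
    """Save frames as zero-padded PNGs; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for f in frames:
        p = out / f"frame_{f.index:05d}.png"
        imgio.save_image(p, f.image)
        paths.append(p)
    return paths


def write_partition_manifest(
    partition: FramePartition,
    frame_paths: dict[int, str | Path],
    out_path: str | os.PathLike,
) -> Path:
    """CSV manifest with columns clip_id,index,path,split."""
    rows = []
    all_frames = (
        [partition.w_t, partition.w_v]
        + partition.test_set
        + partition.val_set
        + partition.unlabeled
    )
    for f in all_frames:
        rows.append(
            {
                "clip_id": f.clip_id,
                "index": f.index,
                "path": str(frame_paths[f.index]),
                "split": partition.split_of(f.index),
            }
        )
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out_path, index=False)
    return out_path
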