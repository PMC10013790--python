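"""Image and mask file I/O.

All in-memory images are float arrays in [0, 1] with shape (H, W, 3); masks
are uint8 arrays with values {0, 1}. On disk, images are 8-bit PNG/JPEG and
masks are single-channel 8-bit PNG with values {0, 255}. Loaders also accept
{0, 1} masks and normalize.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

from .errors import InputError

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg")


def to_float(image: np.ndarray) -> np.ndarray:
    """Convert a uint8 or float image to float32 in [0, 1]."""
    if image.dtype == np.uint8:
        return image.astype(np.float32) / 255.0
    return np.clip(image.astype(np.float32), 0.0, 1.0)


def to_uint8(image: np.ndarray) -> np.ndarray:
    """Quantize a [0, 1] float image to uint8."""
    return np.clip(np.rint(np.asarray(image) * 255.0), 0, 255).astype(np.uint8)


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read an RGB image as float32 in [0, 1], shape (H, W, 3)."""
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read image {path!r}: {exc}") from exc
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    return to_float(arr)


def save_image(path: str | os.PathLike, image: np.ndarray) -> None:
    iio.imwrite(path, to_uint8(image))


def load_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a binary mask as uint8 {0, 1}. Accepts {0, 1} or {0, 255} files."""
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read mask {path!r}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > (arr.max() // 2 if arr.max() > 1 else 0)).astype(np.uint8)


def save_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    """Write a {0,1} (or boolean) mask as single-channel 8-bit PNG {0, 255}."""
    iio.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)


def list_frames(directory: str | os.PathLike) -> list[str]:
    """Sorted image file paths inside ``directory``."""
    names = sorted(
        f for f in os.listdir(directory) if f.lower().endswith(IMAGE_EXTENSIONS)
    )
    return [os.path.join(directory, f) for f in names]
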