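"""Overlap metrics, photometric test-time augmentation, and evaluation reports.

Dice(O, E) = 2|O∩E| / (|O| + |E|) and IoU(O, E) = |O∩E| / |O∪E| between an
observed and an expected binary mask; when both masks are empty the pair is
in perfect agreement and both scores are 1 by convention. TTA predicts on
the original image plus a Gaussian-noise and a Sepia variant — photometric
transforms, so the three binarized predictions align pixelwise — and takes a
per-pixel majority vote (three voters, so no ties).
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from . import imgio
from .errors import InputError
from .manifest import DatasetManifest

SEPIA_MATRIX = np.array(
    [[0.393, 0.769, 0.189], [0.349, 0.686, 0.168], [0.272, 0.534, 0.131]],
    dtype=np.float64,
)


def binarize(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Pixel = 1 iff probability >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise InputError(f"threshold must be in (0,1), got {threshold}")
    return (np.asarray(probs) >= threshold).astype(np.uint8)


def _check_pair(O: np.ndarray, E: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    O = np.asarray(O) > 0
    E = np.asarray(E) > 0
    if O.shape != E.shape:
        raise InputError(f"mask shapes differ: {O.shape} vs {E.shape}")
    return O, E


def dice(O: np.ndarray, E: np.ndarray) -> float:
    """Dice score; both-empty pairs score 1 (0/0 agreement convention)."""
    O, E = _check_pair(O, E)
    denom = O.sum() + E.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(O, E).sum() / denom)


def iou(O: np.ndarray, E: np.ndarray) -> float:
    """Intersection over union; both-empty pairs score 1."""
    O, E = _check_pair(O, E)
    union = np.logical_or(O, E).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(O, E).sum() / union)


def sepia(image: np.ndarray) -> np.ndarray:
    """Fixed 3x3 color-mixing sepia tone, clipped to [0, 1]."""
    return np.clip(np.asarray(image) @ SEPIA_MATRIX.T, 0.0, 1.0).astype(np.float32)


def gaussian_noise(
    image: np.ndarray, sigma: float = 0.05, rng: np.random.Generator | None = None
) -> np.ndarray:
    rng = rng or np.random.default_rng(0)
    return np.clip(image + rng.normal(0.0, sigma, image.shape), 0.0, 1.0).astype(np.float32)


def majority_vote(masks: list[np.ndarray]) -> np.ndarray:
    """Per-pixel majority over an odd number of binary masks."""
    if len(masks) % 2 == 0:
        raise InputError("majority vote needs an odd number of masks")
    stack = np.stack([np.asarray(m) > 0 for m in masks]).astype(np.int32)
    return (stack.sum(axis=0) * 2 > len(masks)).astype(np.uint8)


def _predict_probs_any(model, image: np.ndarray) -> np.ndarray:
    """Probability map from either an estimator or a raw network."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba([image])[0]
    from .model import pad_to_divisor
    from .nn import predict_probs

    h, w = image.shape[:2]
    padded, _ = pad_to_divisor(np.asarray(image, dtype=np.float32), model.divisor)
    return predict_probs(model, padded)[:h, :w]


def tta_predict(
    model, image: np.ndarray, threshold: float = 0.5, rng_seed: int = 0, noise_sigma: float = 0.05
) -> np.ndarray:
    """Majority vote over predictions for the image and two photometric variants."""
    variants = [
        ("original", image),
        ("gaussian-noise", gaussian_noise(image, noise_sigma, np.random.default_rng(rng_seed))),
        ("sepia", sepia(image)),
    ]
    votes = []
    for name, variant in variants:
        try:
            votes.append(binarize(_predict_probs_any(model, variant), threshold))
        except Exception as exc:
            raise RuntimeError(f"TTA variant {name!r} failed: {exc}") from exc
    return majority_vote(votes)


def evaluate(
    model,
    manifest: DatasetManifest,
    tta: bool = False,
    group_by: str | None = "domain",
    threshold: float = 0.5,
    tta_seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Per-image Dice/IoU against manifest ground truth, plus macro summaries.

    Returns a records DataFrame (image_id, domain, dice, iou, tta_used) and a
    summary dict with the overall macro means and, when ``group_by`` is set,
    per-group macro means.
    """
    records = []
    for (_, row), img_path, mask_path in zip(
        manifest.records.iterrows(), manifest.image_paths(), manifest.mask_paths()
    ):
        if mask_path is None or not Path(mask_path).exists():
            raise InputError(f"missing ground-truth mask for record {row['id']}")
        image = imgio.load_image(img_path)
        truth = imgio.load_mask(mask_path)
        if tta:
            pred = tta_predict(model, image, threshold=threshold, rng_seed=tta_seed)
        else:
            pred = binarize(_predict_probs_any(model, image), threshold)
        records.append(
            {
                "image_id": row["id"],
                "domain": row.get("domain", ""),
                "dice": dice(pred, truth),
                "iou": iou(pred, truth),
                "tta_used": bool(tta),
            }
        )
    df = pd.DataFrame(records)
    summary = {
        "n_images": len(df),
        "tta": bool(tta),
        "dice": float(df["dice"].mean()),
        "iou": float(df["iou"].mean()),
    }
    if group_by and group_by in df.columns and df[group_by].nunique() > 0:
        summary["per_group"] = {
            str(name): {"dice": float(g["dice"].mean()), "iou": float(g["iou"].mean()), "n": len(g)}
            for name, g in df.groupby(group_by)
        }
    return df, summary


def save_report(
    df: pd.DataFrame, summary: dict, out_dir: str | os.PathLike, prefix: str = "eval"
) -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / f"{prefix}_records.csv"
    json_path = out / f"{prefix}_summary.json"
    df.to_csv(csv_path, index=False)
    json_path.write_text(json.dumps(summary, indent=2))
    return csv_path, json_path
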