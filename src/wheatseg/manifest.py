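"""Dataset manifests: typed (image, mask, split, stage) records on disk.

A manifest is a CSV with the fixed columns ``id, image_path, mask_path,
split, stage, domain, seed``; paths are stored relative to the manifest's
root directory so a dataset directory can be moved wholesale.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import InputError

MANIFEST_COLUMNS = ["id", "image_path", "mask_path", "split", "stage", "domain", "seed"]


@dataclass
class DatasetManifest:
    """A list of (image, mask) records plus the directory they live in."""

    records: pd.DataFrame
    root: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        self.root = Path(self.root)
        missing = [c for c in MANIFEST_COLUMNS if c not in self.records.columns]
        if missing:
            raise InputError(f"manifest missing columns {missing}")

    def __len__(self) -> int:
        return len(self.records)

    def image_paths(self) -> list[Path]:
        return [self.root / p for p in self.records["image_path"]]

    def mask_paths(self) -> list[Path | None]:
        return [
            self.root / p if isinstance(p, str) and p else None
            for p in self.records["mask_path"].fillna("")
        ]

    def validate_files(self) -> None:
        """Raise InputError if any referenced file is missing or paths repeat."""
        paths = [str(p) for p in self.records["image_path"]]
        if len(set(paths)) != len(paths):
            raise InputError("manifest image paths are not unique")
        for p in self.image_paths():
            if not p.exists():
                raise InputError(f"manifest references missing image {p}")
        for p in self.mask_paths():
            if p is not None and not p.exists():
                raise InputError(f"manifest references missing mask {p}")

    def save(self, path: str | os.PathLike | None = None) -> Path:
        out = Path(path) if path is not None else self.root / "manifest.csv"
        out.parent.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out, index=False)
        return out

    @classmethod
    def load(cls, path: str | os.PathLike) -> "DatasetManifest":
        path = Path(path)
        if not path.exists():
            raise InputError(f"manifest file not found: {path}")
        df = pd.read_csv(path, dtype={"image_path": str, "mask_path": str})
        return cls(records=df, root=path.parent)

    @classmethod
    def from_rows(cls, rows: list[dict], root: str | os.PathLike) -> "DatasetManifest":
        df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
        return cls(records=df, root=Path(root))


def make_row(
    id: str,
    image_path: str,
    mask_path: str = "",
    split: str = "train",
    stage: str = "",
    domain: str = "",
    seed: int = 0,
) -> dict:
    return {
        "id": id,
        "image_path": image_path,
        "mask_path": mask_path,
        "split": split,
        "stage": stage,
        "domain": domain,
        "seed": seed,
    }
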