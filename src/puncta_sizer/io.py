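"""Disk formats: 16-bit TIFF fields, CSV tables, JSON reports.

Fields are written as two-page TIFFs (page 0 = DNA/YOYO-1 channel,
page 1 = dCas9/ATTO550 channel), values clipped to the 16-bit range the
camera would deliver.  Truth manifests and molecule tables are plain
CSV; calibration curves and run configs are JSON (see their own
``to_json`` methods).
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd
import tifffile

from .synthetic import FieldImage

__all__ = ["save_field", "load_field", "save_fields", "load_fields", "save_table"]

U16_MAX = 65535


def _to_uint16(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img), 0, U16_MAX).astype(np.uint16)


def save_field(field: FieldImage, path: Path) -> Path:
    """Write one field as a two-page 16-bit TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.stack([_to_uint16(field.ch1), _to_uint16(field.ch2)]))
    return path


def load_field(path: Path, field_id: str | None = None) -> FieldImage:
    """Read a two-page (or 2xHxW) TIFF back into a FieldImage."""
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim != 3 or arr.shape[0] != 2:
        raise ValueError(f"{path}: expected a 2-channel TIFF, got shape {arr.shape}")
    return FieldImage(
        ch1=arr[0].astype(float),
        ch2=arr[1].astype(float),
        field_id=field_id or path.stem,
    )


def save_fields(fields: Sequence[FieldImage], out_dir: Path) -> List[Path]:
    out_dir = Path(out_dir)
    return [save_field(f, out_dir / f"{f.field_id}.tif") for f in fields]


def load_fields(paths: Sequence[Path]) -> List[FieldImage]:
    return [load_field(p) for p in sorted(Path(p) for p in paths)]


def save_table(df: pd.DataFrame, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
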