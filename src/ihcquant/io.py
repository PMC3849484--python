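"""Image and tabular input/output.

Images are 24-bit RGB brightfield captures, read from TIFF or PNG into
H x W x 3 uint8 arrays; an alpha channel is dropped and grayscale input is
promoted to three identical channels. Per-image results are exported as a
plain CSV count table.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "read_image",
    "write_image",
    "write_count_table",
    "read_count_table",
    "COUNT_TABLE_COLUMNS",
]

COUNT_TABLE_COLUMNS = (
    "image_id",
    "macro_used",
    "n_objects",
    "total_object_area",
    "estimated_nuclei",
)


def read_image(path: Union[str, Path]) -> np.ndarray:
    """Read a TIFF or PNG image as an H x W x 3 uint8 RGB array.

    Raises ``IOError`` naming the path for unreadable files, and
    ``ValueError`` for channel depths above 8 bits.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    if arr.dtype != np.uint8:
        raise ValueError(
            f"{path}: unsupported bit depth {arr.dtype}; expected 8 bits/channel"
        )
    if arr.ndim == 2:  # grayscale -> three identical channels
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path}: unsupported image layout with shape {arr.shape}")
    return np.ascontiguousarray(arr)


def write_image(image: np.ndarray, path: Union[str, Path]) -> None:
    """Write an RGB uint8 array as TIFF or PNG (by file extension)."""
    arr = np.asarray(image)
    if arr.dtype != np.uint8 or arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("write_image expects an H x W x 3 uint8 array")
    try:
        iio.imwrite(Path(path), arr)
    except Exception as exc:
        raise IOError(f"cannot write image file {path}: {exc}") from exc


def write_count_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    """Export a per-image count table as UTF-8 CSV with '.' decimals."""
    missing = [c for c in COUNT_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    out = table.loc[:, list(COUNT_TABLE_COLUMNS)].copy()
    if len(out):
        bad = out[out["estimated_nuclei"] < out["n_objects"]]
        if len(bad):
            raise ValueError(
                "invalid count table rows (estimated_nuclei < n_objects): "
                f"{bad['image_id'].tolist()}"
            )
    try:
        out.to_csv(path, index=False, encoding="utf-8")
    except OSError as exc:
        raise IOError(f"cannot write count table {path}: {exc}") from exc


def read_count_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a CSV produced by :func:`write_count_table`."""
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except OSError as exc:
        raise IOError(f"cannot read count table {path}: {exc}") from exc
    missing = [c for c in COUNT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table {path} missing columns: {missing}")
    df["image_id"] = df["image_id"].astype(str)
    return df.loc[:, list(COUNT_TABLE_COLUMNS)]
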