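"""Image and table I/O: 8-bit grayscale rasters and feature CSVs."""
from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .segment import PatchGrid

__all__ = ["read_image", "write_image", "read_mask", "write_mask",
           "features_to_frame", "write_features_csv"]


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale image and rescale it to [0, 1].

    Color inputs are reduced to luminance; 16-bit inputs are scaled by
    their dtype maximum so one global intensity convention holds.
    """
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    info_max = np.iinfo(arr.dtype).max if np.issubdtype(arr.dtype, np.integer) else 1.0
    return np.asarray(arr, dtype=float) / info_max


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 1] float raster as 8-bit grayscale."""
    arr = np.clip(np.asarray(image, dtype=float), 0, 1)
    iio.imwrite(Path(path), (np.round(arr * 255)).astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    """Binary mask from an image file: any non-zero pixel is foreground."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=-1)
    return (np.asarray(arr) > 0).astype(np.uint8)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool).astype(np.uint8) * 255))


def features_to_frame(features: np.ndarray, grid: PatchGrid) -> pd.DataFrame:
    """Feature matrix as a table with patch coordinates, sorted by (row, col)."""
    rows = np.repeat(np.arange(grid.n_rows), grid.n_cols)
    cols = np.tile(np.arange(grid.n_cols), grid.n_rows)
    df = pd.DataFrame(features, columns=list(FEATURE_NAMES))
    df.insert(0, "patch_col", cols)
    df.insert(0, "patch_row", rows)
    return df


def write_features_csv(path: str | Path, features: np.ndarray, grid: PatchGrid) -> None:
    features_to_frame(features, grid).to_csv(path, index=False)
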