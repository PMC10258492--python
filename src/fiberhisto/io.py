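"""Reading and writing calibrated histology images, label masks and tables.

All metrics downstream are in micrometers; the raster containers carry the
pixels-per-micrometer calibration explicitly, and calibration never alters
stored pixel values — it is applied only when metrics are extracted.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "CalibratedImage",
    "LabelMask",
    "read_image",
    "read_label_mask",
    "write_image",
    "write_label_mask",
    "write_fiber_table",
    "read_fiber_table",
    "write_summary_table",
    "FIBER_TABLE_COLUMNS",
]

#: Column schema of per-fiber tables (CSV and XLSX).
FIBER_TABLE_COLUMNS = [
    "source_id",
    "fiber_id",
    "lesser_diameter_um",
    "area_um2",
    "centroid_x_px",
    "centroid_y_px",
]


@dataclass
class CalibratedImage:
    """8-bit RGB raster with a spatial calibration.

    Parameters
    ----------
    pixels
        (height, width, 3) uint8 array.
    px_per_um
        Pixels per micrometer; the default acquisition setup of the
        workflow this package models resolves 6.6 px/µm at ×60.
    source_id
        Free-text identifier carried into per-fiber records.
    """

    pixels: np.ndarray
    px_per_um: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"expected (H, W, 3) RGB array, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if not np.isfinite(self.px_per_um) or self.px_per_um <= 0:
            raise ValueError(f"px_per_um must be positive, got {self.px_per_um}")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be uint8; use read_image for conversion")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class LabelMask:
    """Integer label raster: 0 = background/connective tissue, k >= 1 = fiber k."""

    labels: np.ndarray
    px_per_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"expected 2-D label array, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        if not np.isfinite(self.px_per_um) or self.px_per_um <= 0:
            raise ValueError(f"px_per_um must be positive, got {self.px_per_um}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def label_ids(self) -> np.ndarray:
        """Sorted distinct nonzero labels."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_labels(self) -> int:
        return int(self.label_ids.size)


def _load_raster(path: str | os.PathLike) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            return tifffile.imread(path)
        return iio.imread(path)
    except Exception as exc:
        raise OSError(f"could not decode image file {path}: {exc}") from exc


def _to_uint8(channel: np.ndarray) -> np.ndarray:
    if channel.dtype == np.uint8:
        return channel
    ch = channel.astype(np.float64)
    lo, hi = ch.min(), ch.max()
    if hi == lo:
        return np.zeros(ch.shape, dtype=np.uint8)
    return np.round((ch - lo) / (hi - lo) * 255.0).astype(np.uint8)


def read_image(path: str | os.PathLike, px_per_um: float) -> CalibratedImage:
    """Read a TIFF/PNG histology image and attach its calibration.

    Non-8-bit data is rescaled per channel to 0..255 by linear min-max
    scaling; grayscale input is replicated across the three channels; an
    alpha channel, if present, is dropped.
    """
    if not np.isfinite(px_per_um) or px_per_um <= 0:
        raise ValueError(f"px_per_um must be positive, got {px_per_um}")
    arr = _load_raster(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"unsupported image shape {arr.shape} in {path}")
    if arr.dtype != np.uint8:
        arr = np.stack([_to_uint8(arr[..., k]) for k in range(3)], axis=-1)
    return CalibratedImage(arr, px_per_um, source_id=Path(path).stem)


def read_label_mask(path: str | os.PathLike, px_per_um: float) -> LabelMask:
    """Read a single-channel integer label raster (e.g. an external
    segmenter's output) and attach its calibration."""
    if not np.isfinite(px_per_um) or px_per_um <= 0:
        raise ValueError(f"px_per_um must be positive, got {px_per_um}")
    arr = _load_raster(path)
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise ValueError(f"label mask must be single-channel, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.floating):
        if not np.all(arr == np.round(arr)):
            raise ValueError(f"label mask {path} contains non-integral values")
        arr = np.round(arr).astype(np.int64)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"label mask {path} has non-integer dtype {arr.dtype}")
    if arr.size and arr.min() < 0:
        raise ValueError(f"label mask {path} contains negative values")
    return LabelMask(arr.astype(np.int32), px_per_um)


def write_image(image: CalibratedImage, path: str | os.PathLike) -> None:
    """Write an RGB image as TIFF (preferred) or PNG, by extension."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, image.pixels, photometric="rgb")
    else:
        iio.imwrite(path, image.pixels)


def write_label_mask(mask: LabelMask, path: str | os.PathLike) -> None:
    """Write a label mask as single-channel TIFF/PNG, by extension."""
    path = Path(path)
    labels = mask.labels
    if labels.size == 0 or labels.max() < 2**16:
        labels = labels.astype(np.uint16)
    else:
        labels = labels.astype(np.int32)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, labels)
    else:
        iio.imwrite(path, labels)


def _records_frame(records: Iterable) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    if not rows:
        return pd.DataFrame(columns=FIBER_TABLE_COLUMNS)
    return pd.DataFrame(rows)[FIBER_TABLE_COLUMNS]


def write_fiber_table(records: Sequence, path: str | os.PathLike) -> None:
    """Write one row per fiber. CSV by default; XLSX when the path ends
    in ``.xlsx``, mirroring spreadsheet-based downstream analysis."""
    df = _records_frame(records)
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False, float_format="%.6f")


def read_fiber_table(path: str | os.PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such fiber table: {path}")
    if path.suffix.lower() == ".xlsx":
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    missing = [c for c in FIBER_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fiber table {path} is missing columns {missing}")
    return df


def write_summary_table(summaries: Sequence, path: str | os.PathLike) -> None:
    """Write one row per section summary (CSV, or XLSX by extension)."""
    rows = [dataclasses.asdict(s) for s in summaries]
    df = pd.DataFrame(rows)
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False, float_format="%.6f")
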