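"""Frame-stack and localization-table I/O.

Stacks are multi-page TIFF (16-bit unsigned by convention); acquisition
metadata (pixel pitch, channel, exposure) round-trips through the TIFF
ImageDescription tag as JSON.  Localization tables are plain CSV with the
de-facto SMLM column set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import DimensionError, FormatError, SchemaError

CHANNELS = ("HER2", "CEP17", "DAPI")

#: canonical localization-table columns (coordinates in nanometres)
LOCALIZATION_COLUMNS = (
    "frame",
    "x_nm",
    "y_nm",
    "sigma_nm",
    "photons",
    "background",
    "uncertainty_nm",
)


@dataclass
class FrameStack:
    """A T x H x W stack of camera frames for one acquisition channel.

    ``data`` holds non-negative intensities in ADU.  ``pixel_size_nm`` is the
    physical camera pixel pitch projected into the sample plane.  The default
    30 ms exposure matches the acquisition this toolkit emulates.
    """

    data: np.ndarray
    pixel_size_nm: float = 100.0
    channel: str = "HER2"
    exposure_ms: float = 30.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None, :, :]
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise DimensionError("stack data must be T x H x W with T >= 1")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if np.issubdtype(self.data.dtype, np.floating) and np.any(self.data < 0):
            raise ValueError("stack intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FrameStack)
            and np.array_equal(self.data, other.data)
            and self.pixel_size_nm == other.pixel_size_nm
            and self.channel == other.channel
        )


def write_stack(stack: FrameStack, path) -> None:
    """Write a stack as a multi-page TIFF with JSON metadata."""
    data = np.asarray(stack.data)
    if np.issubdtype(data.dtype, np.floating):
        if np.any(data < 0):
            raise FormatError("cannot write negative-valued float data as TIFF")
        data = data.astype(np.float32)
    meta = {
        "pixel_size_nm": stack.pixel_size_nm,
        "channel": stack.channel,
        "exposure_ms": stack.exposure_ms,
        "metadata": stack.metadata,
    }
    tifffile.imwrite(
        str(path), data, photometric="minisblack", description=json.dumps(meta)
    )


def read_stack(path) -> FrameStack:
    """Read a multi-page TIFF written by :func:`write_stack` (or any TIFF stack)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(str(path)) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description
    except (tifffile.TiffFileError, ValueError) as exc:
        raise FormatError(f"not a readable TIFF file: {path}") from exc
    if data.ndim == 2:
        data = data[None, :, :]
    kwargs = {}
    if desc:
        try:
            meta = json.loads(desc)
            kwargs = {
                "pixel_size_nm": meta.get("pixel_size_nm", 100.0),
                "channel": meta.get("channel", "HER2"),
                "exposure_ms": meta.get("exposure_ms", 30.0),
                "metadata": meta.get("metadata", {}),
            }
        except (json.JSONDecodeError, AttributeError):
            pass
    return FrameStack(data=data, **kwargs)


def split_frames(stack: FrameStack) -> list:
    """Separate a stack into an ordered list of single 2-D frames."""
    return [stack.data[t].copy() for t in range(stack.n_frames)]


def merge_frames(
    images: Sequence[np.ndarray],
    pixel_size_nm: float = 100.0,
    channel: str = "HER2",
    exposure_ms: float = 30.0,
) -> FrameStack:
    """Combine single frames (same shape, given order) back into one stack."""
    images = [np.asarray(im) for im in images]
    if not images:
        raise DimensionError("cannot merge an empty collection of frames")
    shape = images[0].shape
    for im in images:
        if im.shape != shape:
            raise DimensionError("all frames must have the same shape")
    return FrameStack(
        data=np.stack(images, axis=0),
        pixel_size_nm=pixel_size_nm,
        channel=channel,
        exposure_ms=exposure_ms,
    )


def empty_localizations() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in LOCALIZATION_COLUMNS}).astype(
        {"frame": int}
    )


def validate_localizations(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LOCALIZATION_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"localization table missing columns: {missing}")
    return table[list(LOCALIZATION_COLUMNS)]


def write_localizations(table: pd.DataFrame, path) -> None:
    """Serialize a localization table to CSV (12 significant digits)."""
    validate_localizations(table).to_csv(path, index=False, float_format="%.12g")


def read_localizations(path) -> pd.DataFrame:
    """Read a localization CSV, validating the column schema."""
    table = pd.read_csv(path)
    table = validate_localizations(table)
    return table.astype({"frame": int})
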