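"""Raster and table I/O: the pipeline's on-disk contract.

Images are plain uncompressed TIFF, either one two-channel (planar or
interleaved) file or a ``*_red.tif`` / ``*_green.tif`` pair.  Channel
semantics (which plane is the red/LMTK2 channel) are always taken from an
explicit flag, never guessed from metadata.  Tables are UTF-8 CSV with a
header row and '.' decimal separator.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

REGIONS = ("MFG", "aHPC")
STAGES = ("early", "late")

#: canonical group labels, in the order used throughout (the spared
#: endogenous-control group first, then NFT-affected groups)
GROUP_ORDER = ("early-MFG", "early-aHPC", "late-MFG", "late-aHPC")


def group_label(stage: str, region: str) -> str:
    """Canonical '<stage>-<region>' label for one of the four study groups."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
    return f"{stage}-{region}"


def parse_group_label(label: str) -> tuple[str, str]:
    """Inverse of :func:`group_label`: returns ``(stage, region)``."""
    stage, _, region = label.partition("-")
    group_label(stage, region)  # validates
    return stage, region


@dataclass(frozen=True)
class TwoChannelImage:
    """Paired red (LMTK2) and green (phospho-tau) 8-bit intensity rasters.

    Both channels share the same shape; pixel coordinates are 0-based,
    row-major.
    """

    red: np.ndarray
    green: np.ndarray

    def __post_init__(self) -> None:
        red = np.asarray(self.red)
        green = np.asarray(self.green)
        if red.ndim != 2 or green.ndim != 2:
            raise ValueError("channels must be 2-D rasters")
        if red.shape != green.shape:
            raise ValueError(
                f"channel shape mismatch: red {red.shape} vs green {green.shape}"
            )
        for name, arr in (("red", red), ("green", green)):
            if arr.dtype != np.uint8:
                raise ValueError(f"{name} channel must be uint8, got {arr.dtype}")
        object.__setattr__(self, "red", red)
        object.__setattr__(self, "green", green)

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape


def _to_uint8(arr: np.ndarray, path: os.PathLike | str) -> np.ndarray:
    """Accept 8- or 16-bit integer data; 16-bit is rescaled by //257 (full-range linear)."""
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        return (arr // 257).astype(np.uint8)
    raise ValueError(
        f"{path}: unsupported dtype {arr.dtype}; expected uint8 or uint16 TIFF"
    )


def load_two_channel(
    source: str | os.PathLike | tuple[str | os.PathLike, str | os.PathLike],
    *,
    channel_order: str = "rg",
) -> TwoChannelImage:
    """Load a two-channel image from one TIFF or a (red, green) pair of TIFFs.

    Parameters
    ----------
    source
        A single path to a two-channel TIFF (planar ``(2, H, W)`` or
        interleaved ``(H, W, 2)``), or a 2-tuple of single-channel paths.
    channel_order
        ``"rg"`` (first plane / first path is red) or ``"gr"``.  Required
        knowledge -- the reader never guesses which fluorophore is which.
    """
    if channel_order not in ("rg", "gr"):
        raise ValueError("channel_order must be 'rg' or 'gr'")

    if isinstance(source, (tuple, list)):
        if len(source) != 2:
            raise ValueError("a channel pair must have exactly two paths")
        a = _to_uint8(tifffile.imread(source[0]), source[0])
        b = _to_uint8(tifffile.imread(source[1]), source[1])
        if a.ndim != 2 or b.ndim != 2:
            raise ValueError("pair members must be single-channel 2-D TIFFs")
        if a.shape != b.shape:
            raise ValueError(
                f"shape mismatch between pair members: {a.shape} vs {b.shape}"
            )
    else:
        arr = tifffile.imread(source)
        arr = _to_uint8(arr, source)
        if arr.ndim != 3:
            raise ValueError(f"{source}: expected a 2-channel TIFF, got shape {arr.shape}")
        if arr.shape[0] == 2:  # planar
            a, b = arr[0], arr[1]
        elif arr.shape[-1] == 2:  # interleaved
            a, b = arr[..., 0], arr[..., 1]
        else:
            raise ValueError(
                f"{source}: {arr.shape} has more than 2 channels; "
                "split the file or pass a channel pair explicitly"
            )
    if channel_order == "gr":
        a, b = b, a
    return TwoChannelImage(red=a, green=b)


def write_two_channel(img: TwoChannelImage, path: str | os.PathLike) -> None:
    """Write a planar (2, H, W) uint8 uncompressed TIFF, red plane first."""
    stack = np.stack([img.red, img.green])
    tifffile.imwrite(path, stack, photometric="minisblack")


def write_table(rows: pd.DataFrame | Iterable[Mapping], path: str | os.PathLike) -> None:
    """Write rows to CSV (header always present, even for zero rows)."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, index=False, float_format="%.12g")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


MANIFEST_COLUMNS = ("image_path", "case_id", "region", "stage")


def load_manifest(path: str | os.PathLike, *, check_paths: bool = True) -> pd.DataFrame:
    """Load and validate a manifest linking images to case and group labels.

    Columns: image_path, case_id, region in {MFG, aHPC}, stage in
    {early, late}; (region, stage) jointly define the four study groups.
    Relative image paths are resolved against the manifest's directory.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns: {missing}")
    bad_region = set(df["region"]) - set(REGIONS)
    if bad_region:
        raise ValueError(f"manifest has unknown regions {sorted(bad_region)}")
    bad_stage = set(df["stage"]) - set(STAGES)
    if bad_stage:
        raise ValueError(f"manifest has unknown stages {sorted(bad_stage)}")
    base = Path(path).parent
    resolved = [
        str(p) if Path(p).is_absolute() else str(base / p) for p in df["image_path"]
    ]
    df = df.assign(image_path=resolved)
    if check_paths:
        for p in df["image_path"]:
            if not Path(p).exists():
                raise FileNotFoundError(f"manifest references missing image: {p}")
    df["group"] = [group_label(s, r) for s, r in zip(df["stage"], df["region"])]
    return df
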