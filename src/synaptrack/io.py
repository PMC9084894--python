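"""Readers and writers for localization tables, tracks, stacks, and masks.

The canonical localization CSV dialect has µm-unit columns
``frame,x_um,y_um,intensity,precision_um,id``; an nm dialect
(``x [nm]``, ``y [nm]``) common among SMLM table formats is converted on
read/write.  Image stacks, density maps, and masks go through multi-page
TIFF via tifffile.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

LOC_COLUMNS = ["frame", "x_um", "y_um", "intensity", "precision_um", "id"]
_NM_MAP = {"x [nm]": "x_um", "y [nm]": "y_um", "frame": "frame",
           "intensity [photon]": "intensity", "uncertainty [nm]": "precision_um", "id": "id"}

__all__ = [
    "read_localizations", "write_localizations",
    "read_tracks", "write_tracks",
    "read_stack", "write_stack", "read_mask", "write_mask",
    "write_density_map", "write_ground_truth", "read_ground_truth",
]


def write_localizations(table: pd.DataFrame, path: str | Path, dialect: str = "um") -> None:
    """Write a localization table; ``dialect`` is "um" (canonical) or "nm"."""
    out = table.copy()
    for col in LOC_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan if col == "precision_um" else (-1 if col == "id" else 0)
    out = out[LOC_COLUMNS]
    if dialect == "nm":
        out = out.rename(columns={"x_um": "x [nm]", "y_um": "y [nm]",
                                  "precision_um": "uncertainty [nm]"})
        for col in ("x [nm]", "y [nm]", "uncertainty [nm]"):
            out[col] = out[col] * 1000.0
    elif dialect != "um":
        raise ValueError(f"unknown dialect {dialect!r}")
    out.to_csv(path, index=False)


def read_localizations(path: str | Path) -> pd.DataFrame:
    """Read a localization CSV in either the µm or the nm dialect."""
    try:
        table = pd.read_csv(path)
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed localization CSV {path}: {err}") from err
    cols = set(table.columns)
    if {"x [nm]", "y [nm]"} <= cols:
        table = table.rename(columns=_NM_MAP)
        for col in ("x_um", "y_um", "precision_um"):
            if col in table.columns:
                table[col] = table[col] / 1000.0
    missing = {"frame", "x_um", "y_um"} - set(table.columns)
    if missing:
        raise ValueError(f"localization table {path} missing columns: {sorted(missing)}")
    for col in LOC_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan if col == "precision_um" else (-1 if col == "id" else 1.0)
    bad = table[["frame", "x_um", "y_um"]].isna().any(axis=1)
    if bad.any():
        raise ValueError(
            f"malformed rows in {path} at data lines {list(table.index[bad] + 2)}")
    return table[LOC_COLUMNS]


def write_tracks(table: pd.DataFrame, path: str | Path) -> None:
    table[["track_id", "frame", "x_um", "y_um", "intensity"]].to_csv(path, index=False)


def read_tracks(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = {"track_id", "frame", "x_um", "y_um"} - set(table.columns)
    if missing:
        raise ValueError(f"tracks table {path} missing columns: {sorted(missing)}")
    return table


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    """Write a movie or image as (multi-page) 16-bit TIFF."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint16),
                     photometric="minisblack")


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_density_map(counts: np.ndarray, path: str | Path, map_pixel_um: float) -> None:
    """32-bit density map TIFF with the pixel pitch recorded in metadata."""
    tifffile.imwrite(
        path, np.asarray(counts, dtype=np.float32),
        resolution=(1.0 / map_pixel_um, 1.0 / map_pixel_um),
        metadata={"unit": "um", "map_pixel_um": map_pixel_um},
    )


def write_ground_truth(table: pd.DataFrame, path: str | Path) -> None:
    table[["molecule_id", "frame", "x_um", "y_um", "state"]].to_csv(path, index=False)


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
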