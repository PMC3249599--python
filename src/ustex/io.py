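"""Frame and ROI-table readers/writers.

Frames are 8-bit grayscale PNG files or DICOM files from which only the
pixel grid is taken (geometry always comes from configuration, never from
DICOM tags).  ROI tables are plain CSV with the header
``patient_id, expert_id, iteration, x, y, rho, theta``.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from PIL import Image

ROI_TABLE_COLUMNS = ("patient_id", "expert_id", "iteration", "x", "y", "rho", "theta")


class RoiTableError(ValueError):
    """Raised for malformed ROI tables; messages carry 1-based line numbers."""


def read_frame_image(path: str | Path) -> np.ndarray:
    """Read one 8-bit grayscale frame (PNG or DICOM) as a 2-D uint8 array."""
    path = Path(path)
    if path.suffix.lower() in {".dcm", ".dicom"}:
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = np.asarray(ds.pixel_array)
        if arr.ndim != 2:
            raise ValueError(f"{path.name}: DICOM pixel data is not a 2-D grayscale grid")
        if arr.max() > 255 or arr.min() < 0:
            raise ValueError(f"{path.name}: DICOM pixel data is not 8-bit")
        return arr.astype(np.uint8)
    with Image.open(path) as img:
        if img.mode != "L":
            raise ValueError(
                f"{path.name}: expected 8-bit grayscale input, got mode {img.mode!r}"
            )
        return np.asarray(img, dtype=np.uint8)


def write_frame_png(pixels: np.ndarray, path: str | Path) -> None:
    """Write a 2-D uint8 array as an 8-bit grayscale PNG."""
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValueError("frame must be a 2-D array")
    Image.fromarray(arr.astype(np.uint8), mode="L").save(Path(path))


def read_frames(directory: str | Path, pattern: str = "*.png") -> dict[str, np.ndarray]:
    """Read every matching frame in a directory, keyed by file stem."""
    directory = Path(directory)
    return {
        p.stem: read_frame_image(p) for p in sorted(directory.glob(pattern))
    }


def roi_records_to_table(records: Iterable) -> pd.DataFrame:
    """Tabulate :class:`~ustex.geometry.RoiRecord` objects (patches omitted)."""
    rows = [
        {
            "patient_id": r.patient_id,
            "expert_id": r.expert_id,
            "iteration": r.iteration,
            "x": r.center_xy[0],
            "y": r.center_xy[1],
            "rho": r.center_polar[0],
            "theta": r.center_polar[1],
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(ROI_TABLE_COLUMNS))


def write_roi_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write an ROI table as CSV with the canonical header."""
    missing = set(ROI_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise RoiTableError(f"ROI table is missing columns: {sorted(missing)}")
    table.loc[:, list(ROI_TABLE_COLUMNS)].to_csv(path, index=False)


def read_roi_table(path: str | Path) -> pd.DataFrame:
    """Read and validate an ROI table written by :func:`write_roi_table`.

    Malformed rows are reported with their 1-based line numbers.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise RoiTableError(f"{path.name}: empty file") from None
        if header != list(ROI_TABLE_COLUMNS):
            raise RoiTableError(
                f"{path.name}: line 1: bad header {header!r}"
            )
        rows: list[dict] = []
        errors: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(ROI_TABLE_COLUMNS):
                errors.append(f"line {lineno}: expected {len(ROI_TABLE_COLUMNS)} fields, got {len(row)}")
                continue
            try:
                rows.append(
                    {
                        "patient_id": row[0],
                        "expert_id": int(row[1]),
                        "iteration": int(row[2]),
                        "x": int(row[3]),
                        "y": int(row[4]),
                        "rho": float(row[5]),
                        "theta": float(row[6]),
                    }
                )
            except ValueError:
                errors.append(f"line {lineno}: non-numeric coordinate fields")
    if errors:
        raise RoiTableError(f"{path.name}: " + "; ".join(errors))
    return pd.DataFrame(rows, columns=list(ROI_TABLE_COLUMNS)).astype(
        {
            "expert_id": np.int64,
            "iteration": np.int64,
            "x": np.int64,
            "y": np.int64,
            "rho": np.float64,
            "theta": np.float64,
        }
    )
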