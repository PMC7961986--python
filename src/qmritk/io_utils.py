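"""Readers and writers for NIfTI volumes, b-value sidecars, AIF and cohort
CSV tables, plus run configuration."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .outcome_stats import VALID_EVENT_CODES

__all__ = [
    "VolumeImage",
    "read_volume",
    "write_volume",
    "read_mask",
    "read_bvals",
    "write_bvals",
    "read_aif_csv",
    "write_aif_csv",
    "read_cohort",
    "write_results",
]

COHORT_COLUMNS = ["subject_id", "metric", "value", "time_months", "event"]


@dataclass
class VolumeImage:
    """A 3D/4D image grid with voxel spacing and orientation transform."""

    data: np.ndarray
    spacing: tuple
    affine: np.ndarray
    identifier: str = ""

    def __post_init__(self):
        if self.data.ndim not in (3, 4):
            raise ValueError("image data must be 3D or 4D")
        if any(s <= 0 for s in self.spacing[:3]):
            raise ValueError("voxel spacing must be positive")


def read_volume(path) -> VolumeImage:
    """Load a NIfTI volume losslessly (data kept at stored precision)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several parse error types
        raise ValueError(f"cannot parse NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.get_fdata(dtype=np.float64))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeImage(data, spacing, img.affine, identifier=path.stem)


def write_volume(image: VolumeImage, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = nib.Nifti1Image(np.asarray(image.data, dtype=np.float64), image.affine)
    out.header.set_zooms(image.spacing[:3] + tuple(
        1.0 for _ in range(image.data.ndim - 3)))
    nib.save(out, str(path))


def read_mask(path) -> VolumeImage:
    """Read a mask volume; values must be {0, 1}; data becomes boolean."""
    img = read_volume(path)
    vals = np.unique(img.data)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError(f"mask {path} contains non-binary values {vals[:5]}")
    img.data = img.data.astype(bool)
    return img


def read_bvals(path) -> np.ndarray:
    """Plain-text b-value sidecar: one value per line (or whitespace row)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such b-value file: {path}")
    try:
        vals = np.loadtxt(str(path), dtype=float).ravel()
    except ValueError as exc:
        raise ValueError(f"cannot parse b-value file {path}: {exc}") from exc
    if vals.size < 2 or vals[0] != 0 or np.any(np.diff(vals) <= 0):
        raise ValueError(
            f"b-values in {path} must start at 0 and be strictly increasing")
    return vals


def write_bvals(b_values, path) -> None:
    np.savetxt(str(path), np.asarray(b_values, dtype=float), fmt="%.6g")


def read_aif_csv(path):
    """Two-column AIF CSV: time_s, Cp_mM. Returns (times, Cp)."""
    df = pd.read_csv(path)
    for col in ("time_s", "Cp_mM"):
        if col not in df.columns:
            raise ValueError(f"AIF file {path} missing column {col!r}")
    return df["time_s"].to_numpy(float), df["Cp_mM"].to_numpy(float)


def write_aif_csv(times, Cp, path) -> None:
    pd.DataFrame({"time_s": times, "Cp_mM": Cp}).to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Typed, validated cohort table (subject_id, metric, value,
    time_months, event). Bad rows are reported with their line number
    (1-based, counting the header as line 1)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such cohort file: {path}")
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort file {path} missing columns {sorted(missing)}")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    df["time_months"] = pd.to_numeric(df["time_months"], errors="coerce")
    df["event"] = pd.to_numeric(df["event"], errors="coerce")
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        if row["event"] not in VALID_EVENT_CODES:
            raise ValueError(
                f"{path}:{line}: invalid event code {row['event']!r} "
                f"(expected one of {VALID_EVENT_CODES})")
        if not np.isfinite(row["time_months"]) or row["time_months"] <= 0:
            raise ValueError(f"{path}:{line}: follow-up time must be positive")
        if not np.isfinite(row["value"]):
            raise ValueError(f"{path}:{line}: metric value must be numeric")
    df["event"] = df["event"].astype(int)
    return df


def write_results(table: pd.DataFrame, path, columns=None) -> None:
    """Write a results table with a stable column order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if columns is not None:
        table = table[list(columns)]
    table.to_csv(path, index=False)
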