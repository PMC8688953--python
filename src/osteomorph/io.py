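"""Reading and writing volumes, label masks and morphometry reports.

Volumes travel as multi-page TIFF stacks (or a directory of per-slice TIFF
files, read in lexicographic filename order) or as NRRD.  TIFF carries no
trustworthy voxel-size metadata, so a spacing must be supplied explicitly;
NRRD spacing is taken from the header unless overridden.  Reports are
written as flat CSV or JSON keyed by the standard bone-morphometry
abbreviations (Sa.Le, TV, BV, BV/TV, Tb.Th, Ct.Th, ...).
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import _nrrd
from .volume import AttenuationVolume, TissueLabelVolume

__all__ = [
    "read_volume", "write_volume", "read_labels", "write_labels",
    "write_report", "read_report",
]


def _read_tiff_stack(path: Path) -> np.ndarray:
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise ValueError(f"{path}: directory contains no TIFF slices")
        slices = [tifffile.imread(f) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"{path}: slice shapes differ: {shapes}")
        return np.stack(slices, axis=0)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return data


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    if path.is_dir() or path.suffix.lower() in (".tif", ".tiff"):
        return "tiff"
    if path.suffix.lower() == ".nrrd":
        return "nrrd"
    raise ValueError(f"cannot infer volume format from {path}; pass format=")


def read_volume(path, format: str | None = None, spacing_override=None,
                allow_negative: bool = False) -> AttenuationVolume:
    """Read a reconstructed attenuation volume.

    Spacing resolution order: ``spacing_override`` > embedded metadata >
    error.  A missing spacing is never silently defaulted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    spacing = None
    if fmt in ("tiff", "tiff-stack"):
        data = _read_tiff_stack(path)
    elif fmt == "nrrd":
        data, header = _nrrd.read(path)
        spacing = _nrrd.spacing_from_header(header)
    else:
        raise ValueError(f"unknown volume format {fmt!r}")
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D stack, got shape {data.shape}")
    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)
    if spacing is None:
        raise ValueError(
            f"{path}: no voxel spacing in file metadata; pass spacing_override "
            "(per-axis size in micrometres)")
    return AttenuationVolume(np.asarray(data, dtype=np.float64), spacing,
                             allow_negative=allow_negative)


def write_volume(volume: AttenuationVolume, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt in ("tiff", "tiff-stack"):
        tifffile.imwrite(path, volume.data.astype(np.float32))
    elif fmt == "nrrd":
        _nrrd.write(path, volume.data, spacing=volume.spacing)
    else:
        raise ValueError(f"unknown volume format {fmt!r}")


def write_labels(labels: TissueLabelVolume, path, format: str | None = None) -> None:
    """Write a tissue-label volume with lossless integer encoding."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt in ("tiff", "tiff-stack"):
        tifffile.imwrite(path, labels.labels)
    elif fmt == "nrrd":
        _nrrd.write(path, labels.labels, spacing=labels.spacing)
    else:
        raise ValueError(f"unknown label format {fmt!r}")


def read_labels(path, format: str | None = None, spacing=None) -> TissueLabelVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt in ("tiff", "tiff-stack"):
        data = _read_tiff_stack(path)
        if spacing is None:
            raise ValueError("TIFF labels carry no spacing; pass spacing=")
    else:
        data, header = _nrrd.read(path)
        emb = _nrrd.spacing_from_header(header)
        spacing = spacing if spacing is not None else emb
        if spacing is None:
            raise ValueError(f"{path}: no spacing in NRRD header; pass spacing=")
    return TissueLabelVolume(data, tuple(spacing))


def _flatten(report) -> dict:
    if isinstance(report, dict):
        return report
    if hasattr(report, "to_flat_dict"):
        return report.to_flat_dict()
    raise TypeError(f"cannot serialize report of type {type(report)!r}")


def write_report(report, path, format: str | None = None) -> None:
    """Write a morphometry report or group comparison as CSV or JSON.

    Missing values (regions not computed) are written as empty CSV cells /
    JSON nulls; numbers keep full precision.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "csv"
    if isinstance(report, pd.DataFrame):
        if format == "csv":
            report.to_csv(path, index=False)
        elif format == "json":
            report.to_json(path, orient="records", indent=2)
        else:
            raise ValueError(f"unknown report format {format!r}")
        return
    flat = _flatten(report)
    if format == "csv":
        pd.DataFrame([flat]).to_csv(path, index=False)
    elif format == "json":
        clean = {k: (None if isinstance(v, float) and math.isnan(v) else v)
                 for k, v in flat.items()}
        with open(path, "w") as fh:
            json.dump(clean, fh, indent=2)
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path) -> dict:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            return json.load(fh)
    df = pd.read_csv(path)
    return {k: (None if pd.isna(v) else v) for k, v in df.iloc[0].items()}
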