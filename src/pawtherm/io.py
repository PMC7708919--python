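"""File formats and run configuration.

Thermal frames travel either as plain-matrix CSV (one row per pixel row,
Celsius, lossless round-trip) or as 16-bit unsigned rasters in the common
radiometric-TIFF convention ``counts = (T_C + 273.15) / 0.01`` (exact to
0.01 K). Cohort tables, calibration series and score tables are tidy CSV
(comma separator, "." decimal, UTF-8, header row mandatory).
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Dict

import numpy as np
import pandas as pd
import tifffile
import yaml

from pawtherm.radiometry import SCENE_MAX_C, SCENE_MIN_C
from pawtherm.roi import EllipseROI, ThermalFrame
from pawtherm.simulate import CalibrationSeries

__all__ = [
    "read_frame",
    "write_frame",
    "read_calibration_csv",
    "write_calibration_csv",
    "read_layout_json",
    "write_layout_json",
    "RunConfig",
    "config_hash",
]

_RASTER_SCALE_K = 0.01
_KELVIN_OFFSET = 273.15


def write_frame(frame: ThermalFrame, path: str | Path, fmt: str | None = None) -> Path:
    """Write a frame as CSV matrix or 16-bit radiometric TIFF.

    ``fmt`` is "csv" or "raster"; inferred from the suffix when omitted
    (.csv vs .tif/.tiff).
    """
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            for row in frame.values:
                writer.writerow([repr(float(v)) for v in row])
    elif fmt == "raster":
        counts = np.round((frame.values + _KELVIN_OFFSET) / _RASTER_SCALE_K)
        if counts.min() < 0 or counts.max() > np.iinfo(np.uint16).max:
            raise ValueError("frame temperatures out of 16-bit raster range")
        tifffile.imwrite(path, counts.astype(np.uint16))
    else:
        raise ValueError(f"unknown frame format {fmt!r}; expected 'csv' or 'raster'")
    return path


def read_frame(path: str | Path, fmt: str | None = None) -> ThermalFrame:
    """Read a frame written by :func:`write_frame`.

    CSV matrices are validated cell by cell: a non-rectangular matrix,
    a NaN/unparseable cell, or an out-of-scene-range value raises a
    ``ValueError`` naming the offending (row, col).
    """
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "csv":
        rows: list[list[float]] = []
        with path.open(newline="") as fh:
            for r, row in enumerate(csv.reader(fh)):
                if not row:
                    continue
                parsed = []
                for c, cell in enumerate(row):
                    try:
                        val = float(cell)
                    except ValueError as exc:
                        raise ValueError(
                            f"{path}: unparseable cell at ({r}, {c}): {cell!r}"
                        ) from exc
                    if not np.isfinite(val):
                        raise ValueError(f"{path}: non-finite cell at ({r}, {c})")
                    if val < SCENE_MIN_C or val > SCENE_MAX_C:
                        raise ValueError(
                            f"{path}: temperature {val} degC out of scene range "
                            f"at ({r}, {c})"
                        )
                    parsed.append(val)
                rows.append(parsed)
        if not rows:
            raise ValueError(f"{path}: empty frame")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            bad = next(i for i, r in enumerate(rows) if len(r) != len(rows[0]))
            raise ValueError(
                f"{path}: non-rectangular matrix (row {bad} has {len(rows[bad])} "
                f"cells, row 0 has {len(rows[0])})"
            )
        return ThermalFrame(np.array(rows))
    if fmt == "raster":
        counts = tifffile.imread(path)
        if counts.dtype != np.uint16 or counts.ndim != 2:
            raise ValueError(f"{path}: expected a single-plane uint16 raster")
        return ThermalFrame(counts.astype(float) * _RASTER_SCALE_K - _KELVIN_OFFSET)
    raise ValueError(f"unknown frame format {fmt!r}; expected 'csv' or 'raster'")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".tif", ".tiff"):
        return "raster"
    raise ValueError(f"cannot infer frame format from suffix {suffix!r}")


def write_calibration_csv(series: CalibrationSeries, path: str | Path) -> Path:
    path = Path(path)
    series.to_frame().to_csv(path, index=False)
    return path


def read_calibration_csv(path: str | Path) -> CalibrationSeries:
    frame = pd.read_csv(path)
    required = {"reference_c", "reading_c"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: calibration CSV missing columns {sorted(missing)}")
    return CalibrationSeries.from_frame(frame)


def write_layout_json(layout, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps([roi.as_dict() for roi in layout], indent=2))
    return path


def read_layout_json(path: str | Path):
    data = json.loads(Path(path).read_text())
    return tuple(EllipseROI(**entry) for entry in data)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (see ``pawtherm report``).

    ``cohort`` and ``camera`` hold keyword overrides for
    :class:`pawtherm.simulate.CohortConfig` and
    :class:`pawtherm.simulate.CameraModel`; ``layout`` is "default" or a
    path to a layout JSON.
    """

    seed: int = 0
    out_dir: str = "pawtherm_results"
    cohort: Dict[str, Any] = field(default_factory=dict)
    camera: Dict[str, Any] = field(default_factory=dict)
    layout: str = "default"
    frame_format: str = "csv"
    write_frames: bool = False
    ti_scale: str = "celsius"
    selection_day: int | None = None  # default: last study day
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if self.frame_format not in ("csv", "raster"):
            raise ValueError("frame_format must be 'csv' or 'raster'")
        if self.layout != "default" and not Path(self.layout).exists():
            raise ValueError(f"layout path {self.layout!r} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def as_dict(self) -> dict:
        return asdict(self)


def config_hash(config: RunConfig) -> str:
    """Short stable hash of a run configuration, stamped on artifacts."""
    canonical = json.dumps(config.as_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
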