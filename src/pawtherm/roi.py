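"""Elliptical region-of-interest layout and per-ROI pixel statistics.

The standardized acquisition geometry (prone mouse, fixed 20 cm camera
distance, 80x60 px thermal frame) allows a *fixed* layout of seven
elliptical ROIs: one on each wrist joint of the front paws (FL, FR), one
on each ankle joint of the hind paws (HL, HR), and three reference
ellipses along the upper back. ROIs are sized identically for an entire
study; no per-image segmentation is performed.

Discretization convention: pixels are indexed 0-based with x = column,
y = row, y increasing downward; a pixel belongs to an ROI iff its
*center* satisfies the rotated-ellipse inequality <= 1. ROI standard
deviations are population SDs (divide by N).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np

from pawtherm.radiometry import (
    EmissivitySpec,
    SCENE_MAX_C,
    SCENE_MIN_C,
    FUR_EMISSIVITY,
    SKIN_EMISSIVITY,
    correct_apparent_temperature,
)

__all__ = [
    "PAW_LABELS",
    "BACK_LABELS",
    "ELLIPSE_NAME_MAP",
    "ThermalFrame",
    "EllipseROI",
    "ROIStats",
    "ellipse_mask",
    "roi_stats",
    "default_roi_layout",
    "layout_stats",
]

PAW_LABELS: Tuple[str, ...] = ("FL", "FR", "HL", "HR")
BACK_LABELS: Tuple[str, ...] = ("back1", "back2", "back3")

#: Mapping from the legacy ellipse numbering El1-El7 to anatomical sites.
#: The numbering order is a documented convention of this package.
ELLIPSE_NAME_MAP: Dict[str, str] = {
    "El1": "FL",
    "El2": "FR",
    "El3": "HL",
    "El4": "HR",
    "El5": "back1",
    "El6": "back2",
    "El7": "back3",
}

# Base-resolution geometry (80x60 frame): (center_x, center_y, a, b).
# Head to the left; FL/HL on the top edge of the image, FR/HR on the
# bottom; three back references along the body midline y = 30.
_BASE_SHAPE = (60, 80)  # (height, width)
_BASE_LAYOUT: Dict[str, Tuple[float, float, float, float]] = {
    "FL": (22.0, 14.0, 4.0, 3.0),
    "FR": (22.0, 46.0, 4.0, 3.0),
    "HL": (58.0, 14.0, 4.0, 3.0),
    "HR": (58.0, 46.0, 4.0, 3.0),
    "back1": (30.0, 30.0, 4.0, 3.0),
    "back2": (40.0, 30.0, 4.0, 3.0),
    "back3": (50.0, 30.0, 4.0, 3.0),
}
#: Body ellipse used by the phantom generator (cx, cy, a, b) at 80x60.
BASE_BODY_ELLIPSE: Tuple[float, float, float, float] = (40.0, 30.0, 26.0, 12.0)


@dataclass
class ThermalFrame:
    """A 2D raster of surface temperatures in Celsius.

    ``values`` is row-major with row 0 at the top. ``metadata`` carries
    acquisition context (subject id, study day, emissivity spec applied,
    seed) and is never interpreted by the numerics.
    """

    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"frame must be 2D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("frame contains non-finite temperatures")
        if self.values.min() < SCENE_MIN_C or self.values.max() > SCENE_MAX_C:
            raise ValueError(
                f"frame temperatures outside scene range "
                f"[{SCENE_MIN_C}, {SCENE_MAX_C}] degC"
            )

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class EllipseROI:
    """One elliptical ROI in pixel coordinates (0-based, pixel centers).

    ``rotation`` is the angle (radians, counterclockwise in x-right /
    y-down coordinates) between the semi-axis ``a`` and the x axis.
    ``emissivity_role`` selects the tissue emissivity used when the ROI
    is corrected: "skin" (0.98) for bare paws, "fur" (0.94) for the back.
    """

    label: str
    center_x: float
    center_y: float
    semi_axis_a: float
    semi_axis_b: float
    rotation: float = 0.0
    emissivity_role: str = "skin"

    def __post_init__(self) -> None:
        if self.semi_axis_a <= 0 or self.semi_axis_b <= 0:
            raise ValueError("ellipse semi-axes must be > 0")
        if self.emissivity_role not in ("skin", "fur"):
            raise ValueError(
                f"emissivity_role must be 'skin' or 'fur', got {self.emissivity_role!r}"
            )

    @property
    def emissivity(self) -> float:
        return SKIN_EMISSIVITY if self.emissivity_role == "skin" else FUR_EMISSIVITY

    def scaled(self, sx: float, sy: float) -> "EllipseROI":
        """Return the ROI scaled by (sx, sy) about the frame origin."""
        return replace(
            self,
            center_x=self.center_x * sx,
            center_y=self.center_y * sy,
            semi_axis_a=self.semi_axis_a * sx,
            semi_axis_b=self.semi_axis_b * sy,
        )

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "center_x": self.center_x,
            "center_y": self.center_y,
            "semi_axis_a": self.semi_axis_a,
            "semi_axis_b": self.semi_axis_b,
            "rotation": self.rotation,
            "emissivity_role": self.emissivity_role,
        }


@dataclass(frozen=True)
class ROIStats:
    """Pixel statistics over one ROI (population SD)."""

    min_c: float
    max_c: float
    mean_c: float
    sd_c: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")
        if not self.min_c - 1e-9 <= self.mean_c <= self.max_c + 1e-9:
            raise ValueError("ROI stats violate min <= mean <= max")


def ellipse_mask(roi: EllipseROI, frame_shape: Tuple[int, int]) -> np.ndarray:
    """Boolean inclusion mask of an ROI on a frame of ``(height, width)``.

    A pixel (row r, col c) is included iff its center (x=c, y=r)
    satisfies the rotated-ellipse inequality <= 1. Parts of the ellipse
    falling outside the frame are silently clipped; an ROI that covers
    no pixel at all raises ``ValueError``.
    """
    h, w = int(frame_shape[0]), int(frame_shape[1])
    if h <= 0 or w <= 0:
        raise ValueError(f"frame_shape must be positive, got {frame_shape}")
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - roi.center_x
    dy = yy - roi.center_y
    cos_t, sin_t = np.cos(roi.rotation), np.sin(roi.rotation)
    u = dx * cos_t + dy * sin_t
    v = -dx * sin_t + dy * cos_t
    mask = (u / roi.semi_axis_a) ** 2 + (v / roi.semi_axis_b) ** 2 <= 1.0
    if not mask.any():
        raise ValueError(
            f"ROI {roi.label!r} covers no pixel inside frame {frame_shape} "
            "(ROI off-frame)"
        )
    return mask


def roi_stats(
    frame: ThermalFrame,
    roi: EllipseROI,
    correction: EmissivitySpec | None = None,
) -> ROIStats:
    """Min/max/mean/population-SD of the pixels inside an ROI.

    If ``correction`` is given, the masked *apparent* pixel temperatures
    are emissivity-corrected before statistics are taken, so that paw
    (skin) and back (fur) ROIs can each be corrected with their own
    emissivity on the same raw frame.
    """
    mask = ellipse_mask(roi, frame.shape)
    pixels = frame.values[mask]
    if correction is not None:
        pixels = correct_apparent_temperature(pixels, correction)
    return ROIStats(
        min_c=float(pixels.min()),
        max_c=float(pixels.max()),
        mean_c=float(pixels.mean()),
        sd_c=float(pixels.std(ddof=0)),
        n_pixels=int(pixels.size),
    )


def default_roi_layout(frame_shape: Tuple[int, int] = _BASE_SHAPE) -> Tuple[EllipseROI, ...]:
    """The fixed 7-ellipse layout (4 paws + 3 back references).

    Defined at the native 80x60 resolution and scaled linearly to larger
    frames; geometry is deterministic. Frames smaller than 80x60 are
    rejected.
    """
    h, w = int(frame_shape[0]), int(frame_shape[1])
    base_h, base_w = _BASE_SHAPE
    if h < base_h or w < base_w:
        raise ValueError(
            f"frame {frame_shape} smaller than the native {_BASE_SHAPE} layout"
        )
    sx, sy = w / base_w, h / base_h
    rois = []
    for label, (cx, cy, a, b) in _BASE_LAYOUT.items():
        role = "skin" if label in PAW_LABELS else "fur"
        rois.append(
            EllipseROI(label, cx, cy, a, b, 0.0, role).scaled(sx, sy)
        )
    return tuple(rois)


def layout_stats(
    frame: ThermalFrame,
    layout: Tuple[EllipseROI, ...] | None = None,
    reflected_temp_c: float | None = None,
) -> Dict[str, ROIStats]:
    """Statistics for every ROI of a layout, keyed by label.

    With ``reflected_temp_c`` set, each ROI is emissivity-corrected with
    its own tissue role (skin for paws, fur for back) before statistics.
    """
    if layout is None:
        layout = default_roi_layout(frame.shape)
    out: Dict[str, ROIStats] = {}
    for roi in layout:
        spec = None
        if reflected_temp_c is not None:
            spec = EmissivitySpec(roi.emissivity, reflected_temp_c)
        out[roi.label] = roi_stats(frame, roi, correction=spec)
    return out
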