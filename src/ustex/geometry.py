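"""Convex-probe frame geometry: fan masks, polar coordinates, ROI extraction.

The imaging model is a convex (curvilinear) probe whose scan lines emanate
from a virtual point source located above the top edge of the image.  A pixel
is inside the imaging fan when its polar coordinates relative to that source
-- radius ``rho`` (cm) and signed angle ``theta`` (degrees, measured from the
downward vertical through the source, negative to the left, positive to the
right) -- satisfy ``probe_radius <= rho <= depth`` and ``|theta| <= aperture``.

All Cartesian pixel coordinates are 0-based with the origin in the top-left
corner, ``x`` growing to the right (columns) and ``y`` growing downward
(rows).  Analysis windows are half-open: a side-64 ROI centred at ``(cx, cy)``
covers columns ``[cx-32, cx+32)`` and rows ``[cy-32, cy+32)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

#: Physical size of one pixel.  Fixed so that a 64-pixel ROI spans 2.62 cm.
DEFAULT_PIXEL_SPACING_CM = 2.62 / 64  # = 0.0409375 cm / px

#: Side of the square analysis window, in pixels.
DEFAULT_ROI_SIDE = 64

#: Default synthetic frame layout: 400 rows x 500 columns, virtual source
#: 60 px above the top edge on the central column, 30 degree half-aperture.
DEFAULT_FRAME_SHAPE = (400, 500)
DEFAULT_SOURCE_OFFSET_PX = 60.0
DEFAULT_APERTURE_DEG = 30.0
DEFAULT_DEPTH_CM = 16.0


class PolarCoord(NamedTuple):
    """Polar coordinates of a pixel relative to the virtual source."""

    rho_cm: float
    theta_deg: float
    degenerate: bool = False


class RoiBoundsError(ValueError):
    """Raised when an ROI window crosses the image or fan boundary."""


@dataclass
class UltrasoundFrame:
    """A single grayscale B-mode frame plus its acquisition geometry.

    Parameters
    ----------
    pixels
        2-D integer gray levels in ``[0, 255]``.
    pixel_spacing_cm
        Physical size of one (isotropic) pixel in cm.
    source_xy
        Virtual ultrasound source in pixel coordinates ``(x, y)``; ``y`` is
        typically negative (above the image).  Defaults to the central column,
        60 px above the top edge.
    aperture_deg
        Half-angle of the imaging fan.
    depth_cm
        Maximum imaged radius measured from the virtual source.
    probe_radius_cm
        Radius of the probe face (fan inner bound).  Defaults to the distance
        from the source to the top edge of the image along the axis.
    """

    pixels: np.ndarray
    pixel_spacing_cm: float = DEFAULT_PIXEL_SPACING_CM
    source_xy: tuple[float, float] | None = None
    aperture_deg: float = DEFAULT_APERTURE_DEG
    depth_cm: float = DEFAULT_DEPTH_CM
    probe_radius_cm: float | None = None
    _fan_mask: np.ndarray | None = field(default=None, repr=False, compare=False)
    _polar: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("gray levels must lie in [0, 255]")
        self.pixels = px
        if self.pixel_spacing_cm <= 0:
            raise ValueError("pixel_spacing_cm must be positive")
        if self.source_xy is None:
            self.source_xy = ((px.shape[1] - 1) / 2.0, -DEFAULT_SOURCE_OFFSET_PX)
        if self.probe_radius_cm is None:
            sy = self.source_xy[1]
            self.probe_radius_cm = max(0.0, -sy) * self.pixel_spacing_cm

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def polar_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-pixel ``(rho_cm, theta_deg)`` grids (cached)."""
        if self._polar is None:
            h, w = self.pixels.shape
            sx, sy = self.source_xy
            yy, xx = np.mgrid[0:h, 0:w]
            dx = xx - sx
            dy = yy - sy
            rho = np.hypot(dx, dy) * self.pixel_spacing_cm
            theta = np.degrees(np.arctan2(dx, dy))
            self._polar = (rho, theta)
        return self._polar

    @property
    def fan_mask(self) -> np.ndarray:
        """Boolean grid of in-fan pixels (derived from geometry, cached)."""
        if self._fan_mask is None:
            self._fan_mask = compute_fan_mask(
                self.source_xy,
                self.aperture_deg,
                self.depth_cm,
                self.pixels.shape,
                self.pixel_spacing_cm,
                self.probe_radius_cm,
            )
        return self._fan_mask


@dataclass
class RoiRecord:
    """One established region of interest for one patient.

    ``center_polar`` is always consistent with ``center_xy`` under
    :func:`cartesian_to_polar` for the frame the ROI was taken from.
    """

    patient_id: str
    expert_id: int
    iteration: int
    center_xy: tuple[int, int]
    center_polar: tuple[float, float]
    side_px: int
    patch: np.ndarray
    frame_index: int = 0


def cartesian_to_polar(
    point_xy: tuple[float, float], frame: UltrasoundFrame
) -> PolarCoord:
    """Convert pixel coordinates to polar coordinates about the source.

    ``rho`` is the Euclidean pixel distance to the virtual source scaled by
    the pixel spacing; ``theta`` is measured from the downward vertical
    through the source and is signed (negative left, positive right).  A
    point coincident with the source maps to ``(0, 0)`` and is flagged
    degenerate.
    """
    sx, sy = frame.source_xy
    dx = float(point_xy[0]) - sx
    dy = float(point_xy[1]) - sy
    if dx == 0.0 and dy == 0.0:
        return PolarCoord(0.0, 0.0, True)
    rho = float(np.hypot(dx, dy)) * frame.pixel_spacing_cm
    theta = float(np.degrees(np.arctan2(dx, dy)))
    return PolarCoord(rho, theta, False)


def polar_to_cartesian(
    rho_cm: float, theta_deg: float, frame: UltrasoundFrame
) -> tuple[float, float]:
    """Inverse of :func:`cartesian_to_polar` (pixel coordinates)."""
    sx, sy = frame.source_xy
    r_px = rho_cm / frame.pixel_spacing_cm
    t = np.radians(theta_deg)
    return (sx + r_px * np.sin(t), sy + r_px * np.cos(t))


def compute_fan_mask(
    source_xy: tuple[float, float],
    aperture_deg: float,
    depth_cm: float,
    shape: tuple[int, int],
    pixel_spacing_cm: float,
    probe_radius_cm: float = 0.0,
) -> np.ndarray:
    """Boolean grid of pixels inside the imaging fan.

    A pixel belongs to the fan iff ``|theta| <= aperture_deg`` and
    ``probe_radius_cm <= rho <= depth_cm``.
    """
    h, w = shape
    sx, sy = source_xy
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - sx
    dy = yy - sy
    rho = np.hypot(dx, dy) * pixel_spacing_cm
    theta = np.degrees(np.arctan2(dx, dy))
    return (
        (np.abs(theta) <= aperture_deg)
        & (rho >= probe_radius_cm)
        & (rho <= depth_cm)
    )


def extract_roi_patch(
    frame: UltrasoundFrame,
    center_xy: tuple[int, int],
    side: int = DEFAULT_ROI_SIDE,
    check_fan: bool = True,
) -> np.ndarray:
    """Extract the ``side x side`` gray-level window around ``center_xy``.

    No resampling is performed; the window is the half-open slice
    ``[cx - side//2, cx + side//2) x [cy - side//2, cy + side//2)``.

    Raises
    ------
    RoiBoundsError
        If the window crosses the image boundary or leaves the fan; the
        message names the violated bound.
    """
    cx, cy = int(center_xy[0]), int(center_xy[1])
    half = side // 2
    x0, x1 = cx - half, cx + half
    y0, y1 = cy - half, cy + half
    h, w = frame.pixels.shape
    if y0 < 0:
        raise RoiBoundsError(f"ROI window crosses the top image edge (row {y0})")
    if x0 < 0:
        raise RoiBoundsError(f"ROI window crosses the left image edge (col {x0})")
    if y1 > h:
        raise RoiBoundsError(f"ROI window crosses the bottom image edge (row {y1})")
    if x1 > w:
        raise RoiBoundsError(f"ROI window crosses the right image edge (col {x1})")
    if check_fan and not frame.fan_mask[y0:y1, x0:x1].all():
        raise RoiBoundsError("ROI window leaves the imaging fan")
    return frame.pixels[y0:y1, x0:x1].copy()


def make_roi_record(
    frame: UltrasoundFrame,
    patient_id: str,
    expert_id: int,
    iteration: int,
    center_xy: tuple[int, int],
    side: int = DEFAULT_ROI_SIDE,
    frame_index: int = 0,
) -> RoiRecord:
    """Extract a patch and package it as a :class:`RoiRecord`."""
    patch = extract_roi_patch(frame, center_xy, side)
    rho, theta, _ = cartesian_to_polar(center_xy, frame)
    return RoiRecord(
        patient_id=patient_id,
        expert_id=int(expert_id),
        iteration=int(iteration),
        center_xy=(int(center_xy[0]), int(center_xy[1])),
        center_polar=(rho, theta),
        side_px=side,
        patch=patch,
        frame_index=frame_index,
    )
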