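"""Coordinate frames and unit conversions.

Three unit systems appear in junctional-zone microperimetry analysis:

* **pixels** of an imaging frame (MP-SLO or FAF), 0-based, x rightward,
  y downward, origin at the top-left pixel corner;
* **visual degrees**, fovea-centered, x rightward, y **upward** (the
  perimetric convention for stimulus grids);
* **micrometers on the retina**, defined here as pixel coordinates scaled
  by the frame's μm-per-pixel factor (so, like pixels, y runs downward and
  the origin is the top-left corner).

The degree→μm scale is the retinal magnification ``um_per_degree``. No
published calibration accompanies the imaging protocol this package
models, so the emmetropic schematic-eye convention of 291 μm per visual
degree is the default and the constant is carried explicitly on every
:class:`ImageFrame` and surfaced in reports.

Only square fields are supported: ``field_of_view_deg`` applies to both
axes, matching the 30°×30° / 768×768 FAF acquisition geometry.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, InvalidInputError

#: Default retinal magnification, μm of retina per visual degree
#: (emmetropic schematic eye).
DEFAULT_UM_PER_DEGREE = 291.0


class Unit(str, enum.Enum):
    PIXEL = "pixel"
    DEGREE = "degree"
    MICROMETER = "micrometer"


@dataclass(frozen=True)
class ImageFrame:
    """Geometry of one square imaging frame.

    Parameters
    ----------
    field_of_view_deg:
        Field of view in visual degrees (applies to both axes).
    pixel_dims:
        Number of pixels per axis.
    um_per_degree:
        Retinal magnification in μm per visual degree.
    name:
        Optional label ("SLO", "FAF", ...) used in reports and
        frame-mismatch error messages.
    """

    field_of_view_deg: float
    pixel_dims: int
    um_per_degree: float = DEFAULT_UM_PER_DEGREE
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.field_of_view_deg > 0 and math.isfinite(self.field_of_view_deg)):
            raise ConfigurationError("field_of_view_deg must be a positive finite number")
        if not (isinstance(self.pixel_dims, (int, np.integer)) and self.pixel_dims > 0):
            raise ConfigurationError("pixel_dims must be a positive integer")
        if not (self.um_per_degree > 0 and math.isfinite(self.um_per_degree)):
            raise ConfigurationError("um_per_degree must be a positive finite number")

    @property
    def deg_per_pixel(self) -> float:
        return self.field_of_view_deg / self.pixel_dims

    @property
    def um_per_pixel(self) -> float:
        return self.deg_per_pixel * self.um_per_degree

    @property
    def fovea_px(self) -> np.ndarray:
        """Fovea position in pixels: the frame center."""
        c = self.pixel_dims / 2.0
        return np.array([c, c])

    @property
    def fovea_um(self) -> np.ndarray:
        return self.fovea_px * self.um_per_pixel


@dataclass(frozen=True)
class Point2D:
    """A single 2-D coordinate with an explicit unit tag."""

    x: float
    y: float
    unit: Unit
    frame: ImageFrame | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvalidInputError("Point2D coordinates must be finite")

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])


def _as_xy(points) -> np.ndarray:
    xy = np.asarray(points, dtype=float)
    if xy.shape[-1] != 2:
        raise InvalidInputError(f"expected (..., 2) coordinate array, got shape {xy.shape}")
    if not np.all(np.isfinite(xy)):
        raise InvalidInputError("non-finite coordinates")
    return xy


def _convert(points, frame: ImageFrame, expect: Unit, produce: Unit, fn):
    """Apply ``fn`` to raw arrays; unwrap/re-wrap Point2D with unit checking."""
    if isinstance(points, Point2D):
        if points.unit is not expect:
            raise InvalidInputError(f"expected {expect.value} coordinates, got {points.unit.value}")
        out = fn(_as_xy(points.xy))
        return Point2D(float(out[0]), float(out[1]), produce, frame)
    return fn(_as_xy(points))


def pixels_to_micrometers(points, frame: ImageFrame):
    """Scale pixel coordinates to retinal μm (same origin and axes)."""

    def fn(xy):
        if np.any(xy < 0):
            raise InvalidInputError("negative pixel coordinates")
        return xy * frame.um_per_pixel

    return _convert(points, frame, Unit.PIXEL, Unit.MICROMETER, fn)


def micrometers_to_pixels(points, frame: ImageFrame):
    """Inverse of :func:`pixels_to_micrometers`."""
    return _convert(points, frame, Unit.MICROMETER, Unit.PIXEL,
                    lambda xy: xy / frame.um_per_pixel)


def degrees_to_micrometers(points, frame: ImageFrame):
    """Map fovea-centered degree coordinates into frame μm.

    The fovea anchors to the frame center; x stays rightward while the
    upward degree y-axis flips to the downward image y-axis.
    """
    if frame is None:
        raise ConfigurationError("degree→μm conversion needs a frame carrying the fovea anchor")
    fovea = frame.fovea_um
    s = frame.um_per_degree

    def fn(xy):
        out = np.empty_like(xy)
        out[..., 0] = fovea[0] + xy[..., 0] * s
        out[..., 1] = fovea[1] - xy[..., 1] * s
        return out

    return _convert(points, frame, Unit.DEGREE, Unit.MICROMETER, fn)


def micrometers_to_degrees(points, frame: ImageFrame):
    """Inverse of :func:`degrees_to_micrometers`."""
    fovea = frame.fovea_um
    s = frame.um_per_degree

    def fn(xy):
        out = np.empty_like(xy)
        out[..., 0] = (xy[..., 0] - fovea[0]) / s
        out[..., 1] = (fovea[1] - xy[..., 1]) / s
        return out

    return _convert(points, frame, Unit.MICROMETER, Unit.DEGREE, fn)


def degrees_to_pixels(points, frame: ImageFrame):
    """Fovea-centered degrees → frame pixels (via the μm path)."""
    um = degrees_to_micrometers(points, frame)
    if isinstance(um, Point2D):
        return micrometers_to_pixels(um, frame)
    return um / frame.um_per_pixel


def pixels_to_degrees(points, frame: ImageFrame):
    """Frame pixels → fovea-centered degrees."""
    um = pixels_to_micrometers(points, frame)
    if isinstance(um, Point2D):
        return micrometers_to_degrees(um, frame)
    return micrometers_to_degrees(um, frame)
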