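"""Camera field-of-view geometry.

A camera at distance ``D`` from a planar scene captures a rectangle whose size
follows from the sensor resolution, the aspect ratio ``A = res_w / res_h`` and
one of the three field-of-view angles (diagonal, horizontal or vertical).  The
half-width of the captured surface is

    X = D tan(DFOV/2) / sqrt(1 + 1/A**2)
      = D tan(HFOV/2)
      = A D tan(VFOV/2)

and the full extent is ``IW = 2 X`` wide by ``IH = IW / A`` high (metres).
The acquisition loop triggers a frame every ``IW/2`` metres of along-track
travel, which guarantees that every even-indexed (secondary) frame contains
the junction between the two main frames flanking it, and with it any overlap
or gap anomaly to be corrected.

Angles are accepted in degrees, as camera datasheets state them.  No lens
distortion or perspective model is applied: the scene is treated as planar
and fronto-parallel.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .errors import InvalidInputError, UnsupportedFovError

__all__ = [
    "FovKind",
    "CameraSpec",
    "Extent",
    "half_width",
    "image_extent",
    "acquisition_spacing",
    "printed_extent",
]


class FovKind(str, enum.Enum):
    """Which field-of-view angle a camera datasheet provides."""

    DFOV = "dfov"
    HFOV = "hfov"
    VFOV = "vfov"


@dataclass(frozen=True)
class CameraSpec:
    """Optics and sensor parameters defining the captured extent.

    Parameters
    ----------
    res_w, res_h:
        Sensor resolution in pixels; the aspect ratio ``A`` is derived as
        ``res_w / res_h`` rather than supplied separately, which removes one
        source of inconsistency.
    fov_kind:
        Which of the three angles ``fov_deg`` refers to.
    fov_deg:
        Field of view in degrees, strictly between 0 and 180.
    distance_m:
        Camera-to-scene distance ``D`` in metres (``>= 0``).
    """

    res_w: int
    res_h: int
    fov_kind: FovKind
    fov_deg: float
    distance_m: float

    def __post_init__(self) -> None:
        if self.res_w <= 0 or self.res_h <= 0:
            raise InvalidInputError("resolution must be positive")
        if not 0.0 < self.fov_deg < 180.0:
            raise InvalidInputError("fov_deg must lie strictly between 0 and 180")
        if self.distance_m < 0.0:
            raise InvalidInputError("distance_m must be non-negative")
        # Normalise strings ("dfov") to the enum for config-file convenience.
        if not isinstance(self.fov_kind, FovKind):
            object.__setattr__(self, "fov_kind", FovKind(str(self.fov_kind).lower()))

    @property
    def aspect(self) -> float:
        """Aspect ratio ``A = res_w / res_h``."""
        return self.res_w / self.res_h


@dataclass(frozen=True)
class Extent:
    """Captured surface size in metres: ``iw_m = 2 x_m``, ``ih_m = iw_m / A``."""

    iw_m: float
    ih_m: float
    x_m: float


def half_width(camera: CameraSpec) -> float:
    """Half-width ``X = IW/2`` (metres) of the captured surface.

    The branch used depends on which field-of-view angle the camera supplies;
    all three branches agree for a consistent set of angles.
    """
    a = camera.aspect
    t = math.tan(math.radians(camera.fov_deg) / 2.0)
    d = camera.distance_m
    if camera.fov_kind is FovKind.DFOV:
        return d * t / math.sqrt(1.0 + 1.0 / (a * a))
    if camera.fov_kind is FovKind.HFOV:
        return d * t
    if camera.fov_kind is FovKind.VFOV:
        return a * d * t
    raise UnsupportedFovError(f"unsupported fov kind: {camera.fov_kind!r}")


def image_extent(camera: CameraSpec) -> Extent:
    """Full captured extent ``(IW, IH)`` in metres."""
    x = half_width(camera)
    iw = 2.0 * x
    return Extent(iw_m=iw, ih_m=iw / camera.aspect, x_m=x)


def acquisition_spacing(extent: Extent) -> float:
    """Along-track distance between consecutive triggers: ``IW/2`` metres."""
    return extent.iw_m / 2.0


def printed_extent(camera: CameraSpec) -> tuple[float, float]:
    """``(IW, IH)`` truncated to centimetre precision, for display.

    Truncation (floor at two decimals) rather than round-half-up is the
    package's single stated convention for printing extents; full precision
    is always available through :func:`image_extent`.
    """
    ext = image_extent(camera)
    return math.floor(ext.iw_m * 100.0) / 100.0, math.floor(ext.ih_m * 100.0) / 100.0
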