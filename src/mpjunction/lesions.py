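"""Geographic-atrophy lesion geometry.

Traced GA foci are simple closed polygons in FAF-frame micrometers.
This module filters foci below the minimum traceable lesion area
(0.05 mm² by default), computes signed Euclidean stimulus-to-margin
distances — negative inside atrophy, positive outside, with multifocal
containment resolved by the even-odd rule — and evaluates zone
membership for the junctional (±250 μm) and perilesional (0 to +500 μm)
bands around the lesion margin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from shapely.geometry import Point, Polygon
from shapely.geometry.polygon import orient

from .exceptions import InvalidGeometryError, InvalidInputError, NoLesionError

logger = logging.getLogger(__name__)

UM2_PER_MM2 = 1e6

#: Minimum traceable GA focus area, mm².
DEFAULT_MIN_FOCUS_AREA_MM2 = 0.05


@dataclass(frozen=True)
class GAFocus:
    """One traced atrophy focus: a simple polygon in FAF μm.

    Vertices are normalized to counterclockwise orientation on
    construction; the closing edge is implicit.
    """

    vertices_um: np.ndarray  # (n, 2)
    focus_id: str

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices_um, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
            raise InvalidGeometryError(
                f"focus {self.focus_id}: need an (n≥3, 2) vertex array, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise InvalidInputError(f"focus {self.focus_id}: non-finite vertices")
        # drop an explicit closing vertex if present
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        if len(v) < 3:
            raise InvalidGeometryError(f"focus {self.focus_id}: fewer than 3 distinct vertices")
        poly = Polygon(v)
        if not poly.is_valid or poly.area <= 0:
            raise InvalidGeometryError(
                f"focus {self.focus_id}: self-intersecting or zero-area polygon"
            )
        poly = orient(poly, sign=1.0)  # counterclockwise exterior
        object.__setattr__(self, "vertices_um", np.asarray(poly.exterior.coords)[:-1])
        object.__setattr__(self, "_polygon", poly)

    @property
    def polygon(self) -> Polygon:
        return self._polygon  # type: ignore[attr-defined]


def polygon_area(focus: GAFocus) -> float:
    """Focus area in mm² (shoelace magnitude, orientation-independent)."""
    return focus.polygon.area / UM2_PER_MM2


@dataclass
class LesionTracing:
    """All traced GA foci of one eye, FAF μm frame."""

    foci: list[GAFocus]
    eye_id: str = ""
    min_focus_area_mm2: float = DEFAULT_MIN_FOCUS_AREA_MM2

    @property
    def total_area_mm2(self) -> float:
        return float(sum(polygon_area(f) for f in self.foci))

    def __len__(self) -> int:
        return len(self.foci)


def filter_min_area(tracing: LesionTracing) -> LesionTracing:
    """Drop foci below the minimum traceable area; logs dropped focus ids."""
    kept, dropped = [], []
    for f in tracing.foci:
        (kept if polygon_area(f) >= tracing.min_focus_area_mm2 else dropped).append(f)
    if dropped:
        logger.info(
            "eye %s: dropped %d focus/foci below %g mm²: %s",
            tracing.eye_id, len(dropped), tracing.min_focus_area_mm2,
            [f.focus_id for f in dropped],
        )
    return replace(tracing, foci=kept)


@dataclass(frozen=True)
class SignedDistanceResult:
    """Signed stimulus-to-margin distance: negative inside atrophy."""

    stimulus_id: int
    distance_um: float
    nearest_focus_id: str


def signed_distance(point_um, tracing: LesionTracing, stimulus_id: int = -1) -> SignedDistanceResult:
    """Signed Euclidean distance from a point to the nearest lesion margin.

    The unsigned part is the minimum distance over every focus boundary;
    the sign is negative iff the point lies inside an odd number of foci
    (even-odd rule, so nested tracings alternate). A point exactly on a
    margin returns distance 0 with non-negative sign.

    Raises :class:`NoLesionError` for an empty tracing — the caller
    decides policy for lesion-free eyes.
    """
    if not tracing.foci:
        raise NoLesionError(f"eye {tracing.eye_id}: tracing has no retained focus")
    p = Point(np.asarray(point_um, dtype=float))
    dists = [f.polygon.exterior.distance(p) for f in tracing.foci]
    i = int(np.argmin(dists))
    inside = sum(f.polygon.contains(p) for f in tracing.foci) % 2 == 1
    d = float(dists[i])
    return SignedDistanceResult(
        stimulus_id=stimulus_id,
        distance_um=-d if inside else d,
        nearest_focus_id=tracing.foci[i].focus_id,
    )


def signed_distances(points_um: np.ndarray, tracing: LesionTracing,
                     stimulus_ids=None) -> list[SignedDistanceResult]:
    """Vectorized :func:`signed_distance` over an (n, 2) array."""
    if not tracing.foci:
        raise NoLesionError(f"eye {tracing.eye_id}: tracing has no retained focus")
    pts = np.asarray(points_um, dtype=float)
    if stimulus_ids is None:
        stimulus_ids = np.arange(len(pts))
    geoms = shapely.points(pts)
    dmat = np.stack([shapely.distance(geoms, f.polygon.exterior) for f in tracing.foci])
    inside_ct = np.zeros(len(geoms), dtype=int)
    for f in tracing.foci:
        inside_ct += shapely.contains(f.polygon, geoms).astype(int)
    nearest = np.argmin(dmat, axis=0)
    dmin = dmat[nearest, np.arange(len(geoms))]
    signs = np.where(inside_ct % 2 == 1, -1.0, 1.0)
    return [
        SignedDistanceResult(int(sid), float(s * d), tracing.foci[int(k)].focus_id)
        for sid, s, d, k in zip(stimulus_ids, signs, dmin, nearest)
    ]


@dataclass(frozen=True)
class ZoneSpec:
    """A signed-distance band around the lesion margin, inclusive bounds."""

    kind: str
    inner_limit_um: float
    outer_limit_um: float

    def __post_init__(self) -> None:
        if not self.inner_limit_um < self.outer_limit_um:
            raise InvalidInputError("zone requires inner_limit_um < outer_limit_um")

    @classmethod
    def junctional(cls, half_width_um: float = 250.0) -> "ZoneSpec":
        """The ±250 μm band straddling the GA margin."""
        return cls("junctional", -half_width_um, half_width_um)

    @classmethod
    def perilesional(cls, outer_um: float = 500.0) -> "ZoneSpec":
        """The band from the margin to 500 μm outside the lesion."""
        return cls("perilesional", 0.0, outer_um)


def zone_membership(d: SignedDistanceResult | float, zone: ZoneSpec) -> bool:
    """True iff the signed distance lies in [inner, outer], both inclusive.

    A stimulus exactly on the margin (d = 0) counts as inside both the
    junctional and the perilesional zone.
    """
    dist = d.distance_um if isinstance(d, SignedDistanceResult) else float(d)
    return zone.inner_limit_um <= dist <= zone.outer_limit_um
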