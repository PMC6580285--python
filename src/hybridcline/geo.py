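"""Great-circle transects and perpendicular projection of specimens.

A transect is a piecewise path through ordered waypoints; specimen
coordinates are projected perpendicularly onto it, yielding the
along-transect distance X (km) used as the predictor in cline fitting.

Distances use the haversine formula on a sphere of radius 6,371.0 km.
Projection onto a segment uses exact spherical cross-track geometry
(angular coordinates in the segment's great-circle plane), so the foot
of the perpendicular is correct at any latitude or offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

EARTH_RADIUS_KM = 6371.0

# Default transect: Key Largo FL north-northwest to Lakeland GA, then
# west along ~31 N to a terminus near Houston's longitude.  These are
# configurable approximations; analyses with other waypoints simply
# pass their own list.
DEFAULT_WAYPOINTS = [
    (25.0865, -80.4473),   # Key Largo, FL
    (31.0405, -83.0752),   # Lakeland, GA
    (31.0, -95.4),         # western terminus near Houston's longitude
]


@dataclass(frozen=True)
class GeoPoint:
    """A georeferenced position in decimal degrees."""

    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.latitude) and math.isfinite(self.longitude)):
            raise ValueError("coordinates must be finite")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")


@dataclass(frozen=True)
class Transect:
    """Piecewise great-circle path with cumulative along-path distance.

    ``cumulative_km[i]`` is the distance from waypoint 0 to waypoint i;
    it is strictly increasing and starts at 0.
    """

    waypoints: tuple[GeoPoint, ...]
    segment_lengths: tuple[float, ...] = field(default=())
    cumulative_km: tuple[float, ...] = field(default=())

    @property
    def total_length_km(self) -> float:
        return self.cumulative_km[-1]


@dataclass(frozen=True)
class TransectPosition:
    """Result of projecting a point onto a transect.

    ``distance_km`` is the along-transect coordinate X; ``offset_km`` the
    perpendicular distance from the transect; ``segment_index`` the
    segment that received the projection.
    """

    distance_km: float
    offset_km: float
    segment_index: int


def haversine_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance between two points in km.

    Symmetric and non-negative; uses a fixed Earth radius of 6,371.0 km.
    """
    la1, lo1 = math.radians(a.latitude), math.radians(a.longitude)
    la2, lo2 = math.radians(b.latitude), math.radians(b.longitude)
    dlat = la2 - la1
    dlon = lo2 - lo1
    h = math.sin(dlat / 2.0) ** 2 + math.cos(la1) * math.cos(la2) * math.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def build_transect(waypoints: Sequence[GeoPoint | tuple[float, float]]) -> Transect:
    """Build a transect from ordered waypoints.

    Raises ``ValueError`` for fewer than two waypoints or coincident
    consecutive waypoints (a zero-length segment).
    """
    pts = tuple(p if isinstance(p, GeoPoint) else GeoPoint(*p) for p in waypoints)
    if len(pts) < 2:
        raise ValueError("a transect needs at least 2 waypoints")
    seg = []
    for a, b in zip(pts[:-1], pts[1:]):
        d = haversine_km(a, b)
        if d <= 0.0:
            raise ValueError("consecutive waypoints coincide (zero-length segment)")
        seg.append(d)
    cum = [0.0]
    for d in seg:
        cum.append(cum[-1] + d)
    return Transect(waypoints=pts, segment_lengths=tuple(seg), cumulative_km=tuple(cum))


def default_transect() -> Transect:
    """The packaged default Key Largo -> Lakeland GA -> east Texas transect."""
    return build_transect(DEFAULT_WAYPOINTS)


def _unit_vector(p: GeoPoint):
    la, lo = math.radians(p.latitude), math.radians(p.longitude)
    return np.array([
        math.cos(la) * math.cos(lo),
        math.cos(la) * math.sin(lo),
        math.sin(la),
    ])


def project_point(t: Transect, p: GeoPoint) -> TransectPosition:
    """Perpendicular projection of ``p`` onto the transect.

    Exact spherical geometry: for each great-circle segment the foot of
    the perpendicular is found from the point's angular coordinates in
    the segment's great-circle plane; feet falling beyond a segment end
    are clamped to the nearer endpoint.  The candidate with the smallest
    offset wins (ties go to the lower segment index).  Points beyond
    either terminus therefore clamp to X=0 or X=total length rather than
    being rejected.
    """
    pv = _unit_vector(p)
    best: TransectPosition | None = None
    for i, (a, b) in enumerate(zip(t.waypoints[:-1], t.waypoints[1:])):
        u = _unit_vector(a)
        v = _unit_vector(b)
        omega = math.acos(float(np.clip(np.dot(u, v), -1.0, 1.0)))
        e2 = v - np.dot(v, u) * u
        e2 /= np.linalg.norm(e2)
        theta = math.atan2(float(np.dot(pv, e2)), float(np.dot(pv, u)))
        theta = min(omega, max(0.0, theta))
        foot = math.cos(theta) * u + math.sin(theta) * e2
        # atan2(|cross|, dot) is stable for the near-zero angles of
        # points on or near the transect, unlike acos
        offset = EARTH_RADIUS_KM * math.atan2(
            float(np.linalg.norm(np.cross(pv, foot))), float(np.dot(pv, foot)))
        distance = t.cumulative_km[i] + (theta / omega) * t.segment_lengths[i]
        if best is None or offset < best.offset_km:
            best = TransectPosition(distance_km=distance, offset_km=offset, segment_index=i)
    assert best is not None
    return best


def point_at(t: Transect, distance_km: float) -> GeoPoint:
    """Geographic coordinates of the transect point at along-path distance X.

    Great-circle interpolation within a segment, matching the spherical
    geometry used by :func:`project_point`.
    """
    if not 0.0 <= distance_km <= t.total_length_km + 1e-9:
        raise ValueError("distance outside transect")
    d = min(distance_km, t.total_length_km)
    for i, (a, b) in enumerate(zip(t.waypoints[:-1], t.waypoints[1:])):
        if d <= t.cumulative_km[i + 1] or i == len(t.segment_lengths) - 1:
            frac = (d - t.cumulative_km[i]) / t.segment_lengths[i]
            u, v = _unit_vector(a), _unit_vector(b)
            omega = math.acos(float(np.clip(np.dot(u, v), -1.0, 1.0)))
            w = (math.sin((1.0 - frac) * omega) * u
                 + math.sin(frac * omega) * v) / math.sin(omega)
            return GeoPoint(
                math.degrees(math.asin(float(np.clip(w[2], -1.0, 1.0)))),
                math.degrees(math.atan2(w[1], w[0])),
            )
    raise AssertionError("unreachable")


def project_many(t: Transect, points: Sequence[GeoPoint]) -> list[TransectPosition]:
    return [project_point(t, p) for p in points]
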