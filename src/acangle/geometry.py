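"""Angle-section geometry for anterior-segment OCT morphometry.

One radial B-scan is split at the corneal apex into two *angle sections*
(left/right).  Each section carries two segmented boundary polylines in a
per-scan 2-D frame — the posterior cornea / inner corneoscleral wall (ordered
from the apex region toward the periphery) and the anterior iris surface
(ordered from the pupil margin toward the iris root) — plus the manually
localized scleral spur.  Coordinates are in millimetres: x lateral, y axial,
increasing posteriorly (toward the lens).

From these boundaries four scalar parameters are computed per section:

* ``AODSS``  — angle opening distance at the scleral spur: the perpendicular
  distance from the inner wall at the spur to the anterior iris.
* ``AOD750`` — the same distance cast from the wall point 750 µm anterior to
  the spur (offset measured as arc length along the wall).
* ``TISA750`` — trabecular–iris space area: the area enclosed by the AODSS
  segment, the AOD750 segment, the wall and the iris.
* ``LID`` — light intersection distance: the line from the corneal
  endothelial apex that grazes the most protruding point of the iris
  (the supporting line of the iris as seen from the apex) is extended until
  it meets the wall again at a point X; LID is the signed distance from the
  scleral spur to X, negative when X lies anterior to the spur (narrow
  angles), positive when posterior (wide angles).

All intersections are computed segment-by-segment; the first intersection
along the ray direction wins.  Closed (appositional) angles yield metric 0,
not an error; only geometric impossibility is reported as missing.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "GeometryError",
    "SpurOffWallError",
    "InsufficientWallExtentError",
    "IrisNotIntersectedError",
    "DegenerateAngleRegionError",
    "LidUndefinedError",
    "IrisSupportError",
    "BScanSection",
    "AngleMetrics",
    "wall_point_at_offset",
    "compute_aod",
    "compute_tisa750",
    "find_endothelial_apex",
    "compute_lid",
    "measure_section",
    "polyline_arclength",
    "resample_polyline",
]

#: geometric intersection tolerance, mm
TOL = 1e-9
#: maximum allowed distance of the clicked spur from the wall polyline, mm
SPUR_SNAP_TOL = 0.05
#: arc-length offset of the AOD750 / TISA750 anterior boundary, mm
AOD_OFFSET_750 = 0.75
#: half-width of the chord window used to estimate the local wall tangent, mm
#: (a single 5 um segment would make the perpendicular cast hostage to
#: axial segmentation noise; a symmetric chord is exact on circular arcs and
#: second-order accurate on smooth boundaries, and +-0.1 mm keeps the angle
#: noise of the cast near 0.02 rad at 3 um axial noise)
TANGENT_HALF_WINDOW = 0.1
#: distance below which the LID grazing vertex counts as lying on the wall, mm
LID_WALL_TOL = 0.01
#: arc window of the moving average applied to the wall before arc-length
#: bookkeeping, mm.  Independent axial noise inflates raw chord length
#: (sqrt(h^2 + dn^2) per sample), which would drag the "750 um anterior"
#: landmark toward the spur; averaging removes the inflation while biasing a
#: 6.5 mm corneal arc by well under 0.1 um.
WALL_SMOOTH_WINDOW = 0.05


class GeometryError(ValueError):
    """Base class for geometric measurement failures."""


class SpurOffWallError(GeometryError):
    """Scleral spur farther than the snap tolerance from the wall polyline."""


class InsufficientWallExtentError(GeometryError):
    """Wall polyline does not extend far enough anterior to the spur."""


class IrisNotIntersectedError(GeometryError):
    """Perpendicular cast from the wall never meets the iris polyline."""


class DegenerateAngleRegionError(GeometryError):
    """Wall and iris cross inside the TISA region."""


class LidUndefinedError(GeometryError):
    """Supporting ray exits the imaged region without meeting the wall."""


class IrisSupportError(GeometryError):
    """Supporting line re-enters the iris: non-convex support failure."""


# ---------------------------------------------------------------------------
# polyline primitives
# ---------------------------------------------------------------------------

def _as_polyline(a, name: str = "polyline") -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError(f"{name} must be an (n>=2, 2) array of points")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return arr


def polyline_arclength(poly: np.ndarray) -> np.ndarray:
    """Cumulative arc length at each vertex (chord-length parameterization)."""
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(poly: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at (approximately) uniform arc-length spacing.

    Endpoints are preserved exactly; interior samples are linear
    interpolations of the original chords.
    """
    poly = _as_polyline(poly)
    cum = polyline_arclength(poly)
    total = cum[-1]
    n = max(2, int(math.ceil(total / spacing)) + 1)
    s = np.linspace(0.0, total, n)
    x = np.interp(s, cum, poly[:, 0])
    y = np.interp(s, cum, poly[:, 1])
    return np.column_stack([x, y])


def _project_onto_polyline(poly: np.ndarray, p: np.ndarray):
    """Project a point onto a polyline.

    Returns ``(s, q, d)``: arc-length position of the foot point, the foot
    point itself, and the distance from ``p`` to it.
    """
    a = poly[:-1]
    v = poly[1:] - a
    vv = np.einsum("ij,ij->i", v, v)
    vv = np.where(vv < TOL**2, TOL**2, vv)
    t = np.clip(np.einsum("ij,ij->i", p[None, :] - a, v) / vv, 0.0, 1.0)
    feet = a + t[:, None] * v
    d2 = np.einsum("ij,ij->i", feet - p[None, :], feet - p[None, :])
    i = int(np.argmin(d2))
    cum = polyline_arclength(poly)
    s = cum[i] + t[i] * math.sqrt(vv[i])
    return s, feet[i], math.sqrt(d2[i])


def _point_at_arclength(poly: np.ndarray, s: float):
    """Point and unit tangent (toward increasing arc length) at position s."""
    cum = polyline_arclength(poly)
    s = float(np.clip(s, 0.0, cum[-1]))
    i = int(np.searchsorted(cum, s, side="right")) - 1
    i = min(max(i, 0), len(poly) - 2)
    seg = poly[i + 1] - poly[i]
    length = np.linalg.norm(seg)
    if length < TOL:
        tangent = np.array([1.0, 0.0])
    else:
        tangent = seg / length
    pt = poly[i] + tangent * (s - cum[i])
    return pt, tangent


def _ray_polyline_intersections(origin: np.ndarray, direction: np.ndarray,
                                poly: np.ndarray, tmin: float = 0.0):
    """All intersections of the ray ``origin + t*direction`` with a polyline.

    Returns ``(t, s)`` arrays sorted by ray parameter ``t``, where ``s`` is
    the arc-length position of the hit on the polyline.  Segments parallel to
    the ray are skipped.
    """
    a = poly[:-1]
    v = poly[1:] - a
    w = a - origin[None, :]
    denom = direction[0] * v[:, 1] - direction[1] * v[:, 0]
    ok = np.abs(denom) > 1e-14
    t = np.full(len(a), np.nan)
    u = np.full(len(a), np.nan)
    t[ok] = (w[ok, 0] * v[ok, 1] - w[ok, 1] * v[ok, 0]) / denom[ok]
    u[ok] = (w[ok, 0] * direction[1] - w[ok, 1] * direction[0]) / denom[ok]
    seglen = np.linalg.norm(v, axis=1)
    utol = TOL / np.where(seglen < TOL, TOL, seglen)
    hit = ok & (u >= -utol) & (u <= 1 + utol) & (t >= tmin - TOL)
    if not np.any(hit):
        return np.empty(0), np.empty(0)
    cum = polyline_arclength(poly)
    idx = np.nonzero(hit)[0]
    ts = t[idx]
    ss = cum[idx] + np.clip(u[idx], 0.0, 1.0) * seglen[idx]
    order = np.argsort(ts, kind="stable")
    return ts[order], ss[order]


def _strictly_monotone(x: np.ndarray) -> bool:
    d = np.diff(x)
    return bool(np.all(d > 0) or np.all(d < 0))


def _smooth_polyline(poly: np.ndarray, window: float) -> np.ndarray:
    """Moving average over an arc window (edges use truncated windows)."""
    if len(poly) < 3:
        return poly
    spacing = float(np.median(np.linalg.norm(np.diff(poly, axis=0), axis=1)))
    if spacing <= 0:
        return poly
    half = int(round(window / (2.0 * spacing)))
    if half < 1:
        return poly
    n = len(poly)
    csum = np.vstack([np.zeros(2), np.cumsum(poly, axis=0)])
    lo = np.maximum(0, np.arange(n) - half)
    hi = np.minimum(n, np.arange(n) + half + 1)
    return (csum[hi] - csum[lo]) / (hi - lo)[:, None]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BScanSection:
    """One side of one radial B-scan.

    ``posterior_cornea`` runs from the corneal apex region peripherally into
    the corneoscleral inner wall; ``anterior_iris`` runs from the pupil margin
    to the iris root.  Both must progress strictly monotonically in x toward
    the periphery.  ``scleral_spur`` must lie within :data:`SPUR_SNAP_TOL` of
    the wall polyline.
    """

    posterior_cornea: np.ndarray
    anterior_iris: np.ndarray
    scleral_spur: np.ndarray
    side: Literal["left", "right"] = "right"
    meridian_deg: float = 0.0

    def __post_init__(self):
        wall = _as_polyline(self.posterior_cornea, "posterior_cornea")
        iris = _as_polyline(self.anterior_iris, "anterior_iris")
        spur = np.asarray(self.scleral_spur, dtype=float).reshape(2)
        if not np.all(np.isfinite(spur)):
            raise ValueError("scleral_spur must be finite")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if not (0.0 <= float(self.meridian_deg) < 360.0):
            raise ValueError("meridian_deg must lie in [0, 360)")
        if not _strictly_monotone(wall[:, 0]):
            raise ValueError("posterior_cornea must progress strictly monotonically in x")
        if not _strictly_monotone(iris[:, 0]):
            raise ValueError("anterior_iris must progress strictly monotonically in x")
        object.__setattr__(self, "posterior_cornea", wall)
        object.__setattr__(self, "anterior_iris", iris)
        object.__setattr__(self, "scleral_spur", spur)
        # eager spur check so malformed sections fail at construction
        _, _, d = _project_onto_polyline(wall, spur)
        if d > SPUR_SNAP_TOL:
            raise SpurOffWallError(
                f"spur off wall: {d * 1e3:.1f} um from polyline (tol "
                f"{SPUR_SNAP_TOL * 1e3:.0f} um)")

    @functools.cached_property
    def wall(self) -> np.ndarray:
        """Denoised wall polyline used for all arc-length bookkeeping."""
        return _smooth_polyline(self.posterior_cornea, WALL_SMOOTH_WINDOW)

    def spur_arclength(self) -> float:
        """Arc-length position of the (snapped) spur along the wall."""
        s, _, _ = _project_onto_polyline(self.wall, self.scleral_spur)
        return s

    def snapped_spur(self) -> np.ndarray:
        _, q, _ = _project_onto_polyline(self.wall, self.scleral_spur)
        return q


@dataclass
class AngleMetrics:
    """The four scalar angle parameters for one section.

    A metric that could not be computed is ``None`` and carries the failure
    reason in :attr:`failures`.  Closed angles are 0, never missing.
    """

    aodss: float | None = None
    aod750: float | None = None
    tisa750: float | None = None
    lid: float | None = None
    failures: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("aodss", "aod750", "tisa750"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def complete(self) -> bool:
        return not self.failures

    def status(self) -> str:
        if self.complete:
            return "ok"
        return ";".join(f"{k}:{v}" for k, v in sorted(self.failures.items()))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _smoothed_tangent(poly: np.ndarray, s: float) -> np.ndarray:
    """Unit tangent at arc position s from a symmetric chord window."""
    cum = polyline_arclength(poly)
    lo = max(0.0, s - TANGENT_HALF_WINDOW)
    hi = min(cum[-1], s + TANGENT_HALF_WINDOW)
    p_lo, _ = _point_at_arclength(poly, lo)
    p_hi, _ = _point_at_arclength(poly, hi)
    chord = p_hi - p_lo
    norm = np.linalg.norm(chord)
    if norm < TOL:
        return _point_at_arclength(poly, s)[1]
    return chord / norm


def wall_point_at_offset(section: BScanSection, offset: float):
    """Wall point (and unit tangent) ``offset`` mm anterior to the spur.

    The offset is measured as arc length along the posterior cornea /
    inner-wall polyline, anterior meaning toward the apex (the start of the
    polyline).  The tangent points toward the periphery (increasing arc
    length) and is estimated over a symmetric chord window so segmentation
    noise on a single sample spacing cannot tilt the perpendicular cast.
    """
    if offset < 0:
        raise ValueError("offset must be non-negative")
    wall = section.wall
    s_spur = section.spur_arclength()
    s = s_spur - offset
    if s < -TOL:
        raise InsufficientWallExtentError(
            f"insufficient wall extent: need {offset:.3f} mm anterior to the "
            f"spur, wall provides {s_spur:.3f} mm")
    pt, _ = _point_at_arclength(wall, max(s, 0.0))
    return pt, _smoothed_tangent(wall, max(s, 0.0))


def _aod_details(section: BScanSection, offset: float):
    """AOD plus the iris hit point and its arc position (internal)."""
    w, tangent = wall_point_at_offset(section, offset)
    normal = np.array([-tangent[1], tangent[0]])
    iris = section.anterior_iris
    centroid = iris.mean(axis=0)
    if float(np.dot(normal, centroid - w)) < 0:
        normal = -normal
    ts, ss = _ray_polyline_intersections(w, normal, iris, tmin=-1e-6)
    if len(ts) == 0:
        raise IrisNotIntersectedError(
            "iris not intersected by the perpendicular cast from the wall")
    t0 = float(max(ts[0], 0.0))
    hit = w + normal * t0
    return t0, w, hit, float(ss[0])


def compute_aod(section: BScanSection, offset: float) -> float:
    """Angle opening distance at an arc-length offset anterior to the spur.

    ``compute_aod(section, 0)`` is AODSS; ``compute_aod(section, 0.75)`` is
    AOD750.  The distance is cast perpendicular to the local wall tangent
    toward the iris; an iris appositional to the wall at the cast point gives
    0 (closed angle).
    """
    d, _, _, _ = _aod_details(section, offset)
    return d


def compute_tisa750(section: BScanSection) -> float:
    """Trabecular–iris space area over the 750 µm anterior to the spur.

    Area (shoelace, via shapely) of the region bounded anteriorly by the
    AOD750 segment, posteriorly by the AODSS segment, superiorly by the wall
    and inferiorly by the iris.
    """
    aodss, w0, i0, s_i0 = _aod_details(section, 0.0)
    aod750, w1, i1, s_i1 = _aod_details(section, AOD_OFFSET_750)
    if aodss <= TOL and aod750 <= TOL:
        return 0.0
    wall = section.wall
    iris = section.anterior_iris
    cum_w = polyline_arclength(wall)
    cum_i = polyline_arclength(iris)
    s_spur = section.spur_arclength()
    s_ant = s_spur - AOD_OFFSET_750

    # wall chain from the 750 point toward the spur (increasing s)
    sel = (cum_w > s_ant + TOL) & (cum_w < s_spur - TOL)
    wall_chain = wall[sel]
    # iris chain from the AODSS hit back toward the AOD750 hit
    lo, hi = sorted((s_i0, s_i1))
    sel_i = (cum_i > lo + TOL) & (cum_i < hi - TOL)
    iris_chain = iris[sel_i]
    if s_i0 > s_i1:
        iris_chain = iris_chain[::-1]

    pts = [w1, *wall_chain, w0, i0, *iris_chain, i1]
    coords = []
    for p in pts:
        if not coords or np.linalg.norm(p - coords[-1]) > 1e-12:
            coords.append(np.asarray(p, float))
    if len(coords) < 3:
        return 0.0
    poly = Polygon(coords)
    if poly.is_valid:
        return float(poly.area)
    # repair micro self-intersections (segmentation noise at the corners);
    # a genuine wall/iris crossing changes the enclosed area materially
    arr = np.array(coords)
    signed = 0.5 * abs(float(
        np.sum(arr[:, 0] * np.roll(arr[:, 1], -1)
               - np.roll(arr[:, 0], -1) * arr[:, 1])))
    fixed = poly.buffer(0)
    if fixed.area < 1e-8:
        return 0.0
    if abs(signed - fixed.area) <= max(1e-6, 0.01 * fixed.area):
        return float(fixed.area)
    raise DegenerateAngleRegionError(
        "degenerate angle region: wall and iris cross inside the TISA region")


def find_endothelial_apex(posterior_cornea_full: Sequence) -> np.ndarray:
    """Most anterior vertex (minimum y) of the full-width posterior cornea.

    Ties within the intersection tolerance are broken toward the scan centre
    (smallest |x - centre|).
    """
    arr = np.asarray(posterior_cornea_full, dtype=float)
    if arr.size == 0:
        raise ValueError("no boundary: empty posterior cornea polyline")
    arr = arr.reshape(-1, 2)
    ymin = arr[:, 1].min()
    cand = np.nonzero(arr[:, 1] <= ymin + TOL)[0]
    centre = 0.5 * (arr[:, 0].min() + arr[:, 0].max())
    best = cand[np.argmin(np.abs(arr[cand, 0] - centre))]
    return arr[best].copy()


def _supporting_iris_vertex(section: BScanSection, apex: np.ndarray) -> np.ndarray:
    """Iris vertex grazed by the supporting line from the apex.

    The supporting vertex is the one whose apex ray leaves every other iris
    vertex on the posterior side of the line.  On a discrete polyline this is
    the vertex minimizing the polar angle of the apex ray (lateral axis
    oriented toward the periphery of this side); collinear runs are resolved
    by taking the most peripheral grazing vertex.
    """
    V = section.anterior_iris
    d = V - apex[None, :]
    norms = np.linalg.norm(d, axis=1)
    keep = norms > 1e-6
    if not np.any(keep):
        raise IrisSupportError("apex lies on the iris polyline")
    d, V, norms = d[keep], V[keep], norms[keep]
    sigma = 1.0 if np.median(d[:, 0]) >= 0 else -1.0
    theta = np.arctan2(d[:, 1], sigma * d[:, 0])
    tmin = theta.min()
    grazing = np.nonzero(theta <= tmin + 1e-10)[0]
    best = grazing[np.argmax(norms[grazing])]
    return V[best].copy()


def compute_lid(section: BScanSection, apex: Sequence,
                distance: Literal["euclidean", "arc"] = "euclidean") -> float:
    """Signed light intersection distance for one section.

    The supporting line from the corneal endothelial apex grazing the most
    protruding iris vertex is extended beyond the grazing point until it meets
    the wall polyline at X.  The returned value is |X - spur| (Euclidean by
    default; ``distance='arc'`` measures along the wall), negative when X lies
    anterior to the spur (its arc position from the apex is smaller than the
    spur's), positive when posterior.

    Raises :class:`LidUndefinedError` if the ray exits the imaged region
    without meeting the wall (very wide open angle — reported missing, not
    clamped).
    """
    apex = np.asarray(apex, dtype=float).reshape(2)
    wall = section.wall
    pstar = _supporting_iris_vertex(section, apex)
    ray = pstar - apex
    t_p = float(np.linalg.norm(ray))
    if t_p < 1e-9:
        raise IrisSupportError("apex coincides with the iris vertex")
    u = ray / t_p

    s_foot, foot, d_wall = _project_onto_polyline(wall, pstar)
    if d_wall < LID_WALL_TOL:
        # grazing vertex lies on the wall (iris root): X is the vertex itself
        s_x, x_pt = s_foot, foot
    else:
        ts, ss = _ray_polyline_intersections(apex, u, wall, tmin=t_p + 1e-9)
        if len(ts) == 0:
            raise LidUndefinedError(
                "no intersection (wide open, LID undefined)")
        s_x = float(ss[0])
        x_pt = apex + u * float(ts[0])
        # a supporting line must not pass through the iris before the wall
        ti, _ = _ray_polyline_intersections(apex, u, section.anterior_iris,
                                            tmin=t_p + 1e-6)
        if len(ti) and ti[0] < ts[0] - 1e-6:
            raise IrisSupportError("non-convex iris support failure")

    s_spur = section.spur_arclength()
    spur = section.snapped_spur()
    if distance == "arc":
        mag = abs(s_x - s_spur)
    elif distance == "euclidean":
        mag = float(np.linalg.norm(x_pt - spur))
    else:
        raise ValueError("distance must be 'euclidean' or 'arc'")
    if abs(s_x - s_spur) <= 1e-12:
        return 0.0
    return mag if s_x > s_spur else -mag


def measure_section(section: BScanSection, apex: Sequence,
                    lid_distance: Literal["euclidean", "arc"] = "euclidean"
                    ) -> AngleMetrics:
    """All four angle parameters for one section.

    Individually failing metrics are recorded as missing with their reason;
    the remaining metrics are still computed.
    """
    m = AngleMetrics()
    try:
        m.aodss = compute_aod(section, 0.0)
    except GeometryError as e:
        m.failures["aodss"] = str(e)
    try:
        m.aod750 = compute_aod(section, AOD_OFFSET_750)
    except GeometryError as e:
        m.failures["aod750"] = str(e)
    try:
        m.tisa750 = compute_tisa750(section)
    except GeometryError as e:
        m.failures["tisa750"] = str(e)
    try:
        m.lid = compute_lid(section, apex, distance=lid_distance)
    except GeometryError as e:
        m.failures["lid"] = str(e)
    return m
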