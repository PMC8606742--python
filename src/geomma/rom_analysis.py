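"""Range-of-motion summaries and pose-space envelopes.

Per-specimen joint excursions (min/max per degree of freedom) are pooled
across animals by taking the extreme values, giving the total possible range
per DOF.  Full per-frame pose clouds in Euler space (rx, ry, rz in degrees)
are optionally cosine-corrected (one coordinate rescaled by the cosine of
another, de-distorting distances in Euler space) and wrapped in a concave
hull (alpha shape) whose volume, in cubic degrees, measures the 3D motion
envelope.

The alpha criterion has two dialects in the wild: retain a tetrahedron when
its circumsphere radius is at most ``alpha`` (the convention used here,
commensurate with degree-scaled axes), or at most ``1/alpha``.  The dialect
used is recorded on every envelope.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.spatial import ConvexHull, Delaunay

AXIS_LABELS = {"X": 0, "Y": 1, "Z": 2}


@dataclass(frozen=True)
class RangeRecord:
    """Observed excursion of one DOF for one specimen/side (deg or mm)."""

    specimen: str
    side: str
    joint: str
    dof: str
    min_value: float
    max_value: float
    units: str = "deg"

    def __post_init__(self) -> None:
        if self.min_value > self.max_value:
            raise ValueError(
                f"min {self.min_value} exceeds max {self.max_value} for "
                f"{self.specimen}/{self.side} {self.dof}")

    @property
    def total(self) -> float:
        return self.max_value - self.min_value


class PooledRange(NamedTuple):
    min_value: float
    max_value: float
    total: float


class TranslationSummary(NamedTuple):
    pooled_total: float
    mean_total: float


def pooled_range(records: list[RangeRecord]) -> PooledRange:
    """Pool per-specimen extremes of one DOF: min of minima, max of maxima.

    The total possible range is the spread of the pooled extremes; it is
    invariant to record order and duplication, and at least as large as any
    single specimen's range.
    """
    if not records:
        raise ValueError("no records to pool")
    dofs = {(r.joint, r.dof) for r in records}
    if len(dofs) > 1:
        raise ValueError(f"records mix joints/DOFs: {sorted(dofs)}")
    lo = min(r.min_value for r in records)
    hi = max(r.max_value for r in records)
    return PooledRange(lo, hi, hi - lo)


def translation_summary(records: list[RangeRecord]) -> TranslationSummary:
    """Pooled total plus the mean of per-specimen totals for one translation DOF."""
    pooled = pooled_range(records)
    mean_total = float(np.mean([r.total for r in records]))
    return TranslationSummary(pooled.total, mean_total)


@dataclass(frozen=True)
class PoseCloud:
    """N x 3 cloud of joint rotations (rx, ry, rz) in degrees."""

    points: np.ndarray
    corrected: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("pose cloud must be an (N, 3) array")
        if not np.isfinite(pts).all():
            raise ValueError("pose cloud contains non-finite values")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return self.points.shape[0]


def cosine_correct(cloud: PoseCloud, corrected_axis: str | int = "X",
                   modulating_axis: str | int = "Y") -> PoseCloud:
    """Rescale one Euler coordinate by the cosine of another.

    By default the axis of greatest variation (X, abduction-adduction) is
    corrected by the cosine of the long-axis rotation (Y).  The corrected
    coordinate never grows in magnitude, and the correction is odd in the
    corrected axis.  Applying the correction twice is rejected.
    """
    if cloud.corrected:
        raise ValueError("pose cloud is already cosine-corrected")
    ci = AXIS_LABELS.get(corrected_axis, corrected_axis)
    mi = AXIS_LABELS.get(modulating_axis, modulating_axis)
    if ci == mi:
        raise ValueError("corrected and modulating axes must differ")
    pts = cloud.points.copy()
    pts[:, ci] = pts[:, ci] * np.cos(np.radians(pts[:, mi]))
    return PoseCloud(pts, corrected=True)


@dataclass(frozen=True)
class ROMEnvelope:
    """Alpha-shape envelope of a pose cloud.

    ``tetrahedra`` are the retained Delaunay simplices (vertex indices into
    ``points``); ``boundary_facets`` the triangles bounding the retained
    complex; ``volume`` their summed volume in cubic degrees.
    """

    points: np.ndarray
    tetrahedra: np.ndarray
    boundary_facets: np.ndarray
    volume: float
    alpha: float
    dialect: str = "circumradius"
    _delaunay: Delaunay | None = field(default=None, repr=False, compare=False)
    _retained_mask: np.ndarray | None = field(default=None, repr=False,
                                              compare=False)

    def contains(self, query: np.ndarray) -> np.ndarray:
        """Boolean membership of query points in the retained complex."""
        q = np.atleast_2d(np.asarray(query, dtype=float))
        simplex = self._delaunay.find_simplex(q)
        inside = simplex >= 0
        inside[inside] = self._retained_mask[simplex[inside]]
        return inside


def _tet_volumes(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    t = pts[simplices]
    e = t[:, 1:] - t[:, :1]
    return np.abs(np.linalg.det(e)) / 6.0


def _tet_circumradii(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumsphere radius of each tetrahedron (degenerate tets -> inf)."""
    t = pts[simplices]
    a = t[:, 1:] - t[:, :1]                     # (m, 3, 3) edge matrix
    b = 0.5 * (a ** 2).sum(axis=2)              # (m, 3)
    radii = np.full(len(simplices), np.inf)
    det = np.linalg.det(a)
    ok = np.abs(det) > 1e-12
    if ok.any():
        centre = np.linalg.solve(a[ok], b[ok][..., None])[..., 0]
        radii[ok] = np.sqrt((centre ** 2).sum(axis=1))
    return radii


def alpha_hull(cloud: PoseCloud, alpha: float = 20.0,
               dialect: str = "circumradius") -> ROMEnvelope:
    """Concave hull of a pose cloud by the Delaunay alpha criterion.

    Tetrahedralises the cloud and retains tetrahedra whose circumsphere
    radius is <= the threshold (``alpha`` for the ``circumradius`` dialect,
    ``1/alpha`` for the ``reciprocal`` dialect).  The envelope volume is
    non-decreasing in alpha (circumradius dialect) and bounded above by the
    convex-hull volume, reached as alpha -> infinity.
    """
    if dialect == "circumradius":
        threshold = float(alpha)
    elif dialect == "reciprocal":
        if alpha <= 0:
            raise ValueError("reciprocal dialect needs alpha > 0")
        threshold = 1.0 / float(alpha)
    else:
        raise ValueError(f"unknown alpha dialect {dialect!r}")
    pts = cloud.points
    if cloud.n < 4:
        raise ValueError("need at least 4 points for a 3D hull")
    rank = np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-9)
    if rank < 3:
        raise ValueError(
            f"pose cloud is degenerate (affine rank {rank} < 3: "
            f"{'coplanar' if rank == 2 else 'collinear or coincident'})")
    tri = Delaunay(pts)
    radii = _tet_circumradii(pts, tri.simplices)
    mask = radii <= threshold
    retained = tri.simplices[mask]
    volume = float(_tet_volumes(pts, retained).sum()) if len(retained) else 0.0
    facet_count: Counter[tuple[int, ...]] = Counter()
    for tet in retained:
        for face in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)):
            facet_count[tuple(sorted(tet[list(face)]))] += 1
    boundary = np.array([f for f, c in facet_count.items() if c == 1],
                        dtype=int).reshape(-1, 3)
    return ROMEnvelope(points=pts, tetrahedra=retained,
                       boundary_facets=boundary, volume=volume,
                       alpha=float(alpha), dialect=dialect,
                       _delaunay=tri, _retained_mask=mask)


def convex_hull_volume(cloud: PoseCloud) -> float:
    """Convex-hull volume of the cloud (upper bound for any alpha hull)."""
    return float(ConvexHull(cloud.points).volume)


def single_axis_rom_overlay(envelope: ROMEnvelope,
                            model_limits: dict[str, tuple[float, float]],
                            resolution: float = 1e-3) -> dict[str, dict]:
    """Compare single-axis model ROM limits against an experimental envelope.

    For each axis the model's (min, max) single-DOF rotations from the zero
    reference pose define two test points along that axis.  The report gives,
    per direction, whether the model extreme lies inside the envelope, the
    envelope's own extent along the axis from the origin, and the excess by
    which the model limit overshoots the envelope.
    """
    report: dict[str, dict] = {}
    for axis_label, (lo, hi) in model_limits.items():
        ai = AXIS_LABELS.get(axis_label, axis_label)
        entry = {}
        for direction, limit in (("min", float(lo)), ("max", float(hi))):
            unit = np.zeros(3)
            unit[ai] = np.sign(limit) if limit != 0 else 1.0
            point = np.zeros(3)
            point[ai] = limit
            contained = bool(envelope.contains(point)[0])
            extent = _axis_extent(envelope, unit, abs(limit), resolution)
            entry[direction] = {
                "limit": limit,
                "contained": contained,
                "envelope_extent": extent * (np.sign(limit) or 1.0),
                "excess": max(0.0, abs(limit) - extent),
            }
        report[str(axis_label)] = entry
    return report


def _axis_extent(envelope: ROMEnvelope, unit: np.ndarray, upper: float,
                 resolution: float) -> float:
    """Farthest contained distance along a ray from the origin (bisection)."""
    if not envelope.contains(np.zeros(3))[0]:
        return 0.0
    hi_probe = max(upper, float(np.abs(envelope.points).max())) + 1.0
    lo, hi = 0.0, hi_probe
    if envelope.contains(unit * hi)[0]:
        return hi
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if envelope.contains(unit * mid)[0]:
            lo = mid
        else:
            hi = mid
    return lo
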