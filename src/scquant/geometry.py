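"""Pure geometry kernels.

Region membership and polyline–element intersections, total-least-squares
(orthogonal regression) plane fitting, a k-planes (k = 2) alternating fit
for layer detection, in-plane projection, bounding rectangles and nearest
neighbors. Everything here is unit-agnostic; the rest of the package calls
these with nanometer coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import ElementRegion, Polyline

#: Bisection tolerance (nm) for locating a membership-boundary crossing on a
#: polyline segment. Far below the 0.287 nm pixel, so the crossing position is
#: exact for all practical purposes.
BISECTION_TOL_NM = 1e-8

_SIGN_EPS = 1e-12


class DegenerateFitError(ValueError):
    """All candidate fits collapsed (too few points / degenerate clusters)."""


# ---------------------------------------------------------------------------
# region membership


def point_region_distance(p, region: ElementRegion) -> float:
    """Distance from a point to an element region.

    point_cloud: raw Euclidean distance to the nearest cloud point.
    slab: signed distance to the box surface (negative inside).
    """
    p = np.asarray(p, dtype=float).reshape(3)
    if region.kind == "point_cloud":
        if not region.has_cloud:
            raise ValueError(f"region {region.role} has an empty point cloud")
        d, _ = region.tree().query(p)
        return float(d)
    q = region.axes @ (p - region.center)
    excess = np.abs(q) - region.half_extents
    outside = np.maximum(excess, 0.0)
    if np.any(excess > 0):
        return float(np.linalg.norm(outside))
    return float(np.max(excess))  # negative: depth inside


def is_member(p, region: ElementRegion, delta: float | None = None) -> bool:
    """Membership test: within ``delta`` of a cloud, or inside/on a slab."""
    if region.kind == "point_cloud":
        delta = region.delta_nm if delta is None else delta
        if delta is None or delta <= 0:
            raise ValueError("point_cloud membership needs delta > 0")
        return point_region_distance(p, region) <= delta
    return point_region_distance(p, region) <= 0.0


@dataclass(frozen=True)
class Intersection:
    point: np.ndarray
    interior: bool = False  # whole polyline inside the region


def polyline_region_intersection(
    poly: Polyline,
    region: ElementRegion,
    delta: float | None = None,
    from_end: str = "first",
    tol_nm: float = BISECTION_TOL_NM,
) -> Intersection | None:
    """First crossing of the region's membership boundary, walking the
    polyline from the chosen end.

    Returns ``None`` when the polyline never enters the region, and the far
    vertex flagged ``interior`` when it never leaves it. The crossing on the
    straddling segment is located by bisection to ``tol_nm``.
    """
    if from_end not in ("first", "last"):
        raise ValueError("from_end must be 'first' or 'last'")
    pts = poly.points if from_end == "first" else poly.points[::-1]
    member = np.array([is_member(p, region, delta) for p in pts])
    if not member.any():
        return None
    if member.all():
        return Intersection(pts[-1].copy(), interior=True)
    # first index where membership changes relative to the walk start
    flips = np.nonzero(member[1:] != member[:-1])[0]
    i = int(flips[0])
    a, b = pts[i], pts[i + 1]
    inside_t, outside_t = (0.0, 1.0) if member[i] else (1.0, 0.0)
    seg_len = float(np.linalg.norm(b - a))
    n_iter = max(1, math.ceil(math.log2(max(seg_len / tol_nm, 1.0))))
    for _ in range(n_iter):
        mid = 0.5 * (inside_t + outside_t)
        if is_member(a + mid * (b - a), region, delta):
            inside_t = mid
        else:
            outside_t = mid
    t = 0.5 * (inside_t + outside_t)
    return Intersection(a + t * (b - a), interior=False)


# ---------------------------------------------------------------------------
# plane fitting


@dataclass
class PlaneFit:
    centroid: np.ndarray
    normal: np.ndarray
    rms_residual: float
    n_points: int

    def signed_distances(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return (pts - self.centroid) @ self.normal

    @property
    def sse(self) -> float:
        return self.rms_residual**2 * self.n_points


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Canonical orientation: non-negative z component; ties broken by
    non-negative y, then x."""
    for c in (v[2], v[1], v[0]):
        if c > _SIGN_EPS:
            return v
        if c < -_SIGN_EPS:
            return -v
    return v


def fit_plane(points) -> PlaneFit:
    """Orthogonal-regression plane: minimizes the sum of squared orthogonal
    point-to-plane distances. The normal is the eigenvector of the centered
    second-moment matrix with the smallest eigenvalue."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValueError("plane fit needs >= 3 points of shape (n, 3)")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    moment = centered.T @ centered
    evals, evecs = np.linalg.eigh(moment)
    scale = float(evals[-1])
    if scale <= 0 or evals[1] / scale < 1e-12:
        raise DegenerateFitError("points are collinear or coincident")
    normal = _fix_sign(evecs[:, 0].copy())
    rms = math.sqrt(max(float(evals[0]), 0.0) / len(pts))
    return PlaneFit(centroid=centroid, normal=normal, rms_residual=rms, n_points=len(pts))


@dataclass
class TwoPlaneFit:
    plane_a: PlaneFit
    plane_b: PlaneFit
    assignments: np.ndarray  # 0 -> plane_a, 1 -> plane_b
    angle_deg: float
    gap_nm: float
    total_sse: float


def _plane_pair_stats(pa: PlaneFit, pb: PlaneFit) -> tuple[float, float]:
    na, nb = pa.normal, pb.normal
    if float(na @ nb) < 0:
        nb = -nb
    cosang = min(1.0, abs(float(na @ nb)))
    angle = math.degrees(math.acos(cosang))
    mean_normal = na + nb
    norm = np.linalg.norm(mean_normal)
    if norm < 1e-12:  # perpendicular normals; gap along either
        mean_normal = na
    else:
        mean_normal = mean_normal / norm
    gap = abs(float((pb.centroid - pa.centroid) @ mean_normal))
    return angle, gap


def fit_two_planes(
    points,
    n_restarts: int = 10,
    max_iter: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    min_cluster: int = 3,
) -> TwoPlaneFit:
    """Two-plane (k-planes) fit by alternating assignment and refitting.

    Initializations: (i) split by the sign of the single-plane signed
    residual — the fixed point for planted parallel bilayers — and (ii)
    ``n_restarts`` random balanced partitions, guarding against local optima
    such as the longitudinal split of a curved monolayer. The converged
    candidate with the lowest total squared orthogonal residual wins; ties go
    to the smaller inter-normal angle.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 8:
        raise ValueError("two-plane fit needs >= 8 points")
    if rng is None:
        rng = np.random.default_rng(seed)

    single = fit_plane(pts)
    inits: list[np.ndarray] = [(single.signed_distances(pts) >= 0).astype(int)]
    n = len(pts)
    half = n // 2
    for _ in range(n_restarts):
        labels = np.zeros(n, dtype=int)
        labels[rng.permutation(n)[:half]] = 1
        inits.append(labels)

    best: TwoPlaneFit | None = None
    for labels in inits:
        result = _kplanes_once(pts, labels.copy(), max_iter, min_cluster)
        if result is None:
            continue
        if best is None or (
            result.total_sse < best.total_sse - 1e-12
            or (
                abs(result.total_sse - best.total_sse) <= 1e-12
                and result.angle_deg < best.angle_deg
            )
        ):
            best = result
    if best is None:
        raise DegenerateFitError("every two-plane candidate degenerated")
    return best


def _kplanes_once(
    pts: np.ndarray, labels: np.ndarray, max_iter: int, min_cluster: int
) -> TwoPlaneFit | None:
    for _ in range(max_iter):
        if (labels == 0).sum() < min_cluster or (labels == 1).sum() < min_cluster:
            return None
        try:
            pa = fit_plane(pts[labels == 0])
            pb = fit_plane(pts[labels == 1])
        except DegenerateFitError:
            return None
        da = np.abs((pts - pa.centroid) @ pa.normal)
        db = np.abs((pts - pb.centroid) @ pb.normal)
        # ties keep their current label (equidistant points must not collapse
        # an exactly coplanar configuration into one cluster)
        new_labels = np.where(db < da, 1, np.where(da < db, 0, labels))
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    if (labels == 0).sum() < min_cluster or (labels == 1).sum() < min_cluster:
        return None
    try:
        pa = fit_plane(pts[labels == 0])
        pb = fit_plane(pts[labels == 1])
    except DegenerateFitError:
        return None
    da = np.abs((pts - pa.centroid) @ pa.normal)
    db = np.abs((pts - pb.centroid) @ pb.normal)
    sse = float(np.sum(np.minimum(da, db) ** 2))
    # deterministic ordering: plane_a sits lower along the mean normal
    angle, gap = _plane_pair_stats(pa, pb)
    na = pa.normal
    if float(pa.centroid @ na) > float(pb.centroid @ na):
        pa, pb = pb, pa
        labels = 1 - labels
    return TwoPlaneFit(
        plane_a=pa,
        plane_b=pb,
        assignments=labels,
        angle_deg=angle,
        gap_nm=gap,
        total_sse=sse,
    )


# ---------------------------------------------------------------------------
# projection / rectangle / nearest neighbors


def plane_frame(points, plane: PlaneFit) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic in-plane frame (origin, axis1, axis2).

    axis1 is the in-plane direction of largest variance of ``points``; both
    axes carry the same sign convention as plane normals so repeated runs
    produce identical coordinates.
    """
    pts = np.asarray(points, dtype=float)
    n = plane.normal
    # arbitrary but deterministic in-plane basis
    helper = np.eye(3)[int(np.argmin(np.abs(n)))]
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    centered = pts - plane.centroid
    coords = np.column_stack([centered @ u, centered @ v])
    cov = coords.T @ coords
    evals, evecs = np.linalg.eigh(cov)
    w1, w2 = evecs[:, 1], evecs[:, 0]  # descending variance
    axis1 = _fix_sign(w1[0] * u + w1[1] * v)
    axis2 = _fix_sign(w2[0] * u + w2[1] * v)
    return plane.centroid, axis1, axis2


def project_to_plane(points, plane: PlaneFit) -> np.ndarray:
    """Orthogonal projection into the plane's principal in-plane frame.

    Column 0 follows the direction of largest in-plane variance; the
    centroid of the fitted plane maps to the origin.
    """
    origin, axis1, axis2 = plane_frame(points, plane)
    centered = np.asarray(points, dtype=float) - origin
    return np.column_stack([centered @ axis1, centered @ axis2])


@dataclass
class RectFit:
    axes: np.ndarray  # (2, 2) in-plane directions, length axis first
    length_nm: float
    width_nm: float

    @property
    def area_nm2(self) -> float:
        return self.length_nm * self.width_nm


def bounding_rectangle(coords2d) -> RectFit:
    """Axis-aligned bounding rectangle in the projected frame, spanning the
    per-axis minima and maxima."""
    coords = np.asarray(coords2d, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or len(coords) < 2:
        raise ValueError("bounding rectangle needs >= 2 2D points")
    spans = coords.max(axis=0) - coords.min(axis=0)
    if np.all(spans == 0):
        raise DegenerateFitError("all points identical; rectangle undefined")
    order = np.argsort(spans)[::-1]
    axes = np.eye(2)[order]
    return RectFit(axes=axes, length_nm=float(spans[order[0]]), width_nm=float(spans[order[1]]))


def nearest_neighbor_distance(
    p, candidates, exclude_self: bool = False
) -> tuple[float, int]:
    """Minimum Euclidean distance from ``p`` to the candidate set and the
    index attaining it (ties -> lowest index). ``exclude_self`` ignores
    candidates coincident with ``p``."""
    p = np.asarray(p, dtype=float)
    cands = np.asarray(candidates, dtype=float)
    if cands.ndim != 2:
        raise ValueError("candidates must be a 2D array of points")
    d = np.linalg.norm(cands - p, axis=1)
    if exclude_self:
        d = np.where(d == 0.0, np.inf, d)
    if len(d) == 0 or not np.isfinite(d).any():
        raise ValueError("no eligible nearest-neighbor candidate")
    idx = int(np.argmin(d))
    return float(d[idx]), idx


def group_nearest_neighbors(
    queries: np.ndarray, candidates: np.ndarray, exclude_self: bool = False
) -> np.ndarray:
    """Vectorized NN distances from each query to a candidate set.

    With ``exclude_self`` each query skips one zero-distance match (the
    convention for querying a set against itself).
    """
    queries = np.asarray(queries, dtype=float)
    candidates = np.asarray(candidates, dtype=float)
    if len(candidates) == 0 or (exclude_self and len(candidates) < 2):
        return np.full(len(queries), np.nan)
    from scipy.spatial import cKDTree

    tree = cKDTree(candidates)
    if exclude_self:
        d, _ = tree.query(queries, k=2)
        dist = np.where(d[:, 0] == 0.0, d[:, 1], d[:, 0])
    else:
        dist, _ = tree.query(queries)
    return dist
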