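import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from scquant.geometry import (
    DegenerateFitError,
    bounding_rectangle,
    fit_plane,
    fit_two_planes,
    is_member,
    nearest_neighbor_distance,
    point_region_distance,
    polyline_region_intersection,
    project_to_plane,
)
from scquant.model import ElementRegion, Polyline

from conftest import make_slab


def slab_x_below(limit, role="LE_left"):
    """Slab occupying x <= limit (band in a 200-wide box)."""
    return ElementRegion(
        role=role, kind="slab", center=np.array([limit - 100.0, 0, 0]),
        axes=np.eye(3), half_extents=np.array([100.0, 150.0, 150.0]),
    )


def slab_x_above(limit, role="CE"):
    return ElementRegion(
        role=role, kind="slab", center=np.array([limit + 100.0, 0, 0]),
        axes=np.eye(3), half_extents=np.array([100.0, 150.0, 150.0]),
    )


class TestRegionDistance:
    def test_slab_outside_distance(self):
        region = make_slab("CE", 0.0, 10.0, x_half=10.0, z_half=10.0)
        assert point_region_distance([0, 0, 15], region) == pytest.approx(5.0)

    def test_slab_inside_is_negative(self):
        region = make_slab("CE", 0.0, 10.0, x_half=10.0, z_half=10.0)
        assert point_region_distance([0, 0, 2], region) == pytest.approx(-8.0)

    def test_cloud_distance_matches_brute_force(self):
        rng = np.random.default_rng(0)
        cloud = rng.uniform(-50, 50, size=(200, 3))
        region = ElementRegion(role="CE", kind="point_cloud", points=cloud, delta_nm=4.0)
        for p in rng.uniform(-80, 80, size=(20, 3)):
            brute = np.linalg.norm(cloud - p, axis=1).min()
            assert point_region_distance(p, region) == pytest.approx(brute, abs=1e-12)

    def test_membership_boundary(self):
        cloud = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        region = ElementRegion(role="CE", kind="point_cloud", points=cloud, delta_nm=2.0)
        assert is_member([0, 0, 0], region)
        assert is_member([0, 0, 3.001], region, delta=2.0) is False
        assert is_member([3.0, 0, 0], region, delta=2.0)  # exactly delta from (1,0,0)


class TestIntersection:
    def test_straight_tf_segments_reproduce_cohort_means(self):
        # 88 nm filament: 21 inside the LE, 53 midsection, 14 inside the CE
        tf = Polyline(np.linspace([0.0, 0, 0], [88.0, 0, 0], 5))
        le, ce = slab_x_below(21.0), slab_x_above(74.0)
        x_le = polyline_region_intersection(tf, le, from_end="first")
        x_ce = polyline_region_intersection(tf, ce, from_end="last")
        assert x_le.point == pytest.approx([21.0, 0, 0], abs=1e-7)
        assert x_ce.point == pytest.approx([74.0, 0, 0], abs=1e-7)
        assert np.linalg.norm(x_ce.point - x_le.point) == pytest.approx(53.0, abs=1e-6)

    def test_outside_and_interior_cases(self):
        tf = Polyline(np.array([[40.0, 0, 0], [60.0, 0, 0]]))
        assert polyline_region_intersection(tf, slab_x_below(21.0)) is None
        hit = polyline_region_intersection(tf, slab_x_below(100.0), from_end="first")
        assert hit.interior and hit.point == pytest.approx([60.0, 0, 0])

    def test_dense_cloud_converges_to_slab_answer(self):
        # cloud sampled on the slab volume eroded by delta: membership surface
        # approximates the true x = 21 face
        delta, spacing = 2.0, 0.5
        xs = np.arange(-10.0, 21.0 - delta + 1e-9, spacing)
        ys = np.arange(-15.0, 15.0 + 1e-9, spacing)
        zs = np.arange(-6.0, 6.0 + 1e-9, spacing)
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        cloud = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        region = ElementRegion(role="LE_left", kind="point_cloud", points=cloud, delta_nm=delta)
        tf = Polyline(np.linspace([0.0, 0, 0], [88.0, 0, 0], 5))
        hit = polyline_region_intersection(tf, region, delta=delta, from_end="first")
        assert abs(hit.point[0] - 21.0) < 0.6


class TestPlaneFit:
    def test_flat_square(self):
        fit = fit_plane([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
        assert fit.normal == pytest.approx([0, 0, 1])
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_offsets_closed_form(self):
        h = 0.35
        pts = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [0.5, 0.5, h], [0.5, 0.5, -h]]
        fit = fit_plane(pts)
        assert fit.normal == pytest.approx([0, 0, 1])
        assert fit.rms_residual == pytest.approx(h * np.sqrt(2 / 6), rel=1e-12)

    def test_collinear_raises(self):
        with pytest.raises(DegenerateFitError):
            fit_plane([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]])

    def test_beats_random_planes(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(50, 3)) * [10, 6, 1]
        fit = fit_plane(pts)
        centered = pts - pts.mean(axis=0)
        normals = rng.normal(size=(2000, 3))
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        sse = ((centered @ normals.T) ** 2).sum(axis=0)
        assert fit.sse <= sse.min() + 1e-9

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_motion_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(40, 3)) * [8, 5, 0.5]
        rot = Rotation.random(random_state=seed).as_matrix()
        shift = rng.normal(size=3) * 50
        fit0, fit1 = fit_plane(pts), fit_plane(pts @ rot.T + shift)
        assert fit1.rms_residual == pytest.approx(fit0.rms_residual, abs=1e-9)
        assert fit1.centroid == pytest.approx(rot @ fit0.centroid + shift, abs=1e-8)
        assert abs(np.dot(fit1.normal, rot @ fit0.normal)) == pytest.approx(1.0, abs=1e-9)


class TestTwoPlanes:
    @staticmethod
    def bilayer_points(gap, jitter, n, seed):
        # layers extended in x and y so stacking (z) is the thin direction
        rng = np.random.default_rng(seed)
        pts = np.column_stack([
            rng.uniform(0, 100, 2 * n), rng.uniform(0, 100, 2 * n),
            np.repeat([gap / 2, -gap / 2], n) + rng.normal(0, jitter, 2 * n),
        ])
        labels = np.repeat([0, 1], n)
        return pts, labels

    def test_planted_jitter_free_bilayer(self):
        pts, _ = self.bilayer_points(30.0, 0.0, 50, 0)
        fit = fit_two_planes(pts, seed=0)
        assert fit.angle_deg == pytest.approx(0.0, abs=1e-6)
        assert fit.gap_nm == pytest.approx(30.0, abs=1e-6)
        assert fit.total_sse == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_bilayer_assignment_recovery(self, seed):
        pts, labels = self.bilayer_points(30.0, 3.0, 50, seed)
        fit = fit_two_planes(pts, seed=seed)
        agree = (fit.assignments == labels).mean()
        assert max(agree, 1 - agree) >= 0.95

    def test_monolayer_no_spurious_wide_gap(self):
        # splitting pure noise yields gap ~1.6 sigma vs within-rms ~0.6 sigma;
        # over 20 seeds the mean gap/rms ratio must stay at that artifact
        # level (<= 3), never ballooning into a bilayer-like separation
        ratios = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pts = np.column_stack([
                rng.uniform(0, 200, 100), rng.uniform(0, 50, 100), rng.normal(0, 2.0, 100)
            ])
            fit = fit_two_planes(pts, seed=seed)
            ratios.append(fit.gap_nm / np.sqrt(fit.total_sse / len(pts)))
        assert np.mean(ratios) <= 3.0
        assert max(ratios) <= 4.0

    def test_two_plane_sse_never_exceeds_single(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(60, 3)) * [20, 10, 4]
        two = fit_two_planes(pts, seed=0)
        assert two.total_sse <= fit_plane(pts).sse + 1e-9


class TestProjectionRectangle:
    def test_in_plane_distances_preserved(self):
        rng = np.random.default_rng(5)
        pts = np.column_stack([rng.normal(size=(30, 2)) * [10, 3], np.zeros(30)])
        coords = project_to_plane(pts, fit_plane(pts))
        d3 = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d2 = np.linalg.norm(coords[:, None] - coords[None], axis=-1)
        assert d2 == pytest.approx(d3, abs=1e-9)

    def test_height_projects_to_foot_point(self):
        base = np.column_stack([
            np.random.default_rng(0).normal(size=(20, 2)) * [10, 3], np.zeros(20)
        ])
        plane = fit_plane(base)
        lifted = base + [0, 0, 7.0]
        assert project_to_plane(lifted, plane) == pytest.approx(
            project_to_plane(base, plane), abs=1e-9
        )

    def test_projection_deterministic(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(25, 3)) * [10, 4, 0.5]
        plane = fit_plane(pts)
        assert np.array_equal(project_to_plane(pts, plane), project_to_plane(pts, plane))

    def test_rectangle_examples(self):
        rect = bounding_rectangle([[0, 0], [2, 0], [2, 1]])
        assert (rect.length_nm, rect.width_nm, rect.area_nm2) == (2.0, 1.0, 2.0)
        with_interior = bounding_rectangle([[0, 0], [2, 0], [2, 1], [1, 0.5]])
        assert with_interior.area_nm2 == rect.area_nm2

    def test_rectangle_matches_minmax_oracle(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(-5, 9, size=(100, 2))
        rect = bounding_rectangle(pts)
        spans = sorted(pts.max(axis=0) - pts.min(axis=0), reverse=True)
        assert (rect.length_nm, rect.width_nm) == pytest.approx(spans)

    def test_rectangle_degenerate(self):
        with pytest.raises(DegenerateFitError):
            bounding_rectangle([[1.0, 2.0], [1.0, 2.0]])


class TestNearestNeighbor:
    def test_examples(self):
        d, i = nearest_neighbor_distance([0, 0, 0], [[3, 4, 0], [1, 1, 1]])
        assert d == pytest.approx(np.sqrt(3)) and i == 1
        d, i = nearest_neighbor_distance([1, 1, 1], [[1, 1, 1], [0, 1, 1]], exclude_self=True)
        assert d == pytest.approx(1.0) and i == 1

    def test_tie_prefers_lowest_index(self):
        d, i = nearest_neighbor_distance([0, 0, 0], [[0, 0, 2], [0, 2, 0], [2, 0, 0]])
        assert d == pytest.approx(2.0) and i == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 100, size=(500, 3))
        for p in pts[:25]:
            d, i = nearest_neighbor_distance(p, pts, exclude_self=True)
            dists = np.linalg.norm(pts - p, axis=1)
            dists[dists == 0] = np.inf
            assert d == dists.min() and i == int(np.argmin(dists))
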