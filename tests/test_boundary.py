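"""Boundary kinematics and cortical quantification: Pratt curvature against
a geometric least-squares oracle, signed motion/area bookkeeping, section
building, normalization and region partition."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from protrudyn.boundary import (
    CorticalSections,
    assign_regions,
    build_cortical_sections_frame,
    compute_kinematics,
    local_area_change,
    local_curvature,
    normalize_intensity,
    normalize_unassigned,
    polygon_area,
    pratt_circle_fit,
    region_levels,
    sections_from_field,
    track_boundary_points,
)


def _geometric_circle_fit(pts):
    """Oracle: nonlinear least squares on the geometric distances."""
    x, y = pts[:, 0], pts[:, 1]

    def residuals(p):
        cx, cy, r = p
        return np.hypot(x - cx, y - cy) - r

    cx0, cy0 = x.mean(), y.mean()
    r0 = np.hypot(x - cx0, y - cy0).mean()
    sol = least_squares(residuals, [cx0, cy0, r0])
    return sol.x[2]


def _circle(n=100, r=1.0, center=(0.0, 0.0), phase=0.0):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False) + phase
    return np.column_stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)])


class TestCurvature:
    def test_pratt_matches_geometric_oracle_on_random_arcs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            r = rng.uniform(0.5, 20.0)
            c = rng.uniform(-10, 10, 2)
            th0 = rng.uniform(0, 2 * np.pi)
            span = rng.uniform(0.2, 1.5)
            th = th0 + np.linspace(0, span, 11)
            pts = np.column_stack([c[0] + r * np.cos(th), c[1] + r * np.sin(th)])
            _, r_pratt = pratt_circle_fit(pts)
            r_oracle = _geometric_circle_fit(pts)
            assert abs(r_pratt - r_oracle) / r_oracle < 1e-6

    def test_circle_curvature_half_inverse_micron(self):
        kappa = local_curvature(_circle(100, 2.0))
        assert np.allclose(kappa, 0.5, atol=1e-3)

    def test_straight_segment_zero(self):
        pts = np.column_stack([np.linspace(0, 10, 11), np.zeros(11)])
        _, r = pratt_circle_fit(pts)
        assert r == np.inf

    def test_concave_region_negative(self):
        """An inward dent on a counterclockwise boundary has negative curvature."""
        th = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        r = 6.0 - 1.5 * np.exp(-(((th - np.pi) / 0.25) ** 2))
        pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
        kappa = local_curvature(pts)
        assert kappa[np.argmin(r)] < 0
        assert kappa[0] > 0


class TestPointTracking:
    def test_uniform_dilation_all_outward(self):
        prev = _circle(100, 6.0)
        nxt = _circle(100, 6.5)
        shift, motion = track_boundary_points(prev, nxt)
        assert shift == 0
        assert np.allclose(motion, 0.5, atol=1e-6)

    def test_pure_translation_signed_sum_near_zero(self):
        prev = _circle(100, 6.0)
        nxt = prev + np.array([0.4, 0.1])
        shift, motion = track_boundary_points(prev, nxt)
        # oracle: exact point-in-polygon classification of displaced points
        from shapely.geometry import Point, Polygon

        poly = Polygon(prev)
        matched = np.roll(nxt, -shift, axis=0)
        for k in range(100):
            expect_inward = poly.contains(Point(*matched[k]))
            assert (motion[k] < 0) == expect_inward or motion[k] == 0
        assert abs(motion.sum()) < 0.05 * np.abs(motion).sum()

    def test_growing_bump_localized(self, bump_cell):
        params, series, _, truth = bump_cell
        ev = truth.events.iloc[0]
        t = int(ev["birth_frame"])
        shift, motion = track_boundary_points(series.points[t], series.points[t + 1])
        rel = series.points[t] - truth.centroid_path[t]
        theta = np.arctan2(rel[:, 1], rel[:, 0])
        d = np.abs((theta - ev["angle"] + np.pi) % (2 * np.pi) - np.pi)
        near = d < 0.5
        step = params.centroid_speed * params.frame_interval
        # bump growth dominates the translation component near the event
        assert motion[near].max() > motion[~near].max()
        assert motion[near].max() > step


class TestAreaChange:
    def test_static_boundary_zero(self):
        pts = _circle(100, 6.0)
        shift, motion = track_boundary_points(pts, pts)
        a, flags = local_area_change(pts, pts, shift, motion)
        assert np.allclose(a, 0.0)

    def test_uniform_dilation_closed_form(self):
        r, d = 6.0, 0.3
        prev, nxt = _circle(100, r), _circle(100, r + d)
        shift, motion = track_boundary_points(prev, nxt)
        a, _ = local_area_change(prev, nxt, shift, motion)
        expected = np.pi * ((r + d) ** 2 - r**2)
        assert abs(a.sum() / expected - 1) < 0.01

    def test_random_smooth_deformations_conserve_area(self):
        """Σ a_k equals the total polygon area change within 5% across 50
        random smooth star-convex deformations (shoelace oracle)."""
        rng = np.random.default_rng(1)
        th = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        worst = 0.0
        for _ in range(50):
            c1 = rng.uniform(-0.4, 0.4, 3)
            c2 = c1 + rng.uniform(-0.25, 0.25, 3)
            r1 = 6.0 + c1[0] * np.sin(th) + c1[1] * np.cos(2 * th) + c1[2] * np.sin(3 * th)
            r2 = 6.2 + c2[0] * np.sin(th) + c2[1] * np.cos(2 * th) + c2[2] * np.sin(3 * th)
            prev = np.column_stack([r1 * np.cos(th), r1 * np.sin(th)])
            nxt = np.column_stack([r2 * np.cos(th), r2 * np.sin(th)])
            shift, motion = track_boundary_points(prev, nxt)
            a, _ = local_area_change(prev, nxt, shift, motion)
            delta = polygon_area(nxt) - polygon_area(prev)
            worst = max(worst, abs((a.sum() - delta) / delta))
        assert worst < 0.05


@pytest.fixture(scope="module")
def frame_sections(rendered_quiet):
    from protrudyn.segmentation import extract_boundary, segment_frame

    _, truth, movie = rendered_quiet
    marker = movie.channel("cell_marker")
    labels = segment_frame(marker[0])
    pts = extract_boundary(labels, marker[0], movie.voxel_size_xy,
                           label_id=1, origin=movie.origin)
    return truth, movie, labels, pts, marker


class TestCorticalSections:

    def test_voxel_conservation(self, frame_sections):
        truth, movie, labels, pts, marker = frame_sections
        n_k, _, _, n_un, _ = build_cortical_sections_frame(
            pts, labels > 0, marker[0], movie.voxel_size_xy, origin=movie.origin
        )
        assert n_k.sum() + n_un == (labels > 0).sum()

    def test_uniform_intensity_flat_sections(self, frame_sections):
        truth, movie, labels, pts, marker = frame_sections
        uniform = np.where(labels > 0, 3.0, 0.0).astype(float)
        _, raw_k, cmean, _, _ = build_cortical_sections_frame(
            pts, labels > 0, uniform, movie.voxel_size_xy, origin=movie.origin
        )
        assert np.nanstd(raw_k) < 1e-9
        assert cmean == pytest.approx(3.0)

    def test_rear_pool_peaks_in_rear_arc(self, frame_sections):
        truth, movie, labels, pts, marker = frame_sections
        _, raw_k, _, _, _ = build_cortical_sections_frame(
            pts, labels > 0, marker[0], movie.voxel_size_xy, origin=movie.origin
        )
        centroid = pts.mean(axis=0)
        theta = np.arctan2(pts[:, 1] - centroid[1], pts[:, 0] - centroid[0])
        heading = truth.headings[0]
        k_max = np.nanargmax(raw_k)
        d = abs((theta[k_max] - (heading + np.pi) + np.pi) % (2 * np.pi) - np.pi)
        assert d <= 0.3 * np.pi  # within the true rear arc


class TestNormalization:
    def _sections(self, raw):
        raw = np.asarray(raw, float)
        return CorticalSections(
            raw=raw,
            counts=np.ones_like(raw),
            cell_mean=raw.mean(axis=1),
            unassigned_raw=np.full(raw.shape[0], 2.0),
            unassigned_counts=np.full(raw.shape[0], 5.0),
        )

    def test_global_min_maps_to_zero_and_mean_to_one(self):
        rng = np.random.default_rng(3)
        raw = rng.uniform(1.0, 4.0, (5, 100))
        secs = self._sections(raw)
        i_norm, _, flat = normalize_intensity(secs)
        assert np.nanmin(i_norm) == 0.0
        assert not flat.any()
        # a section sitting exactly at the frame mean maps to 1
        t, k = np.unravel_index(np.argmin(raw), raw.shape)
        raw2 = raw.copy()
        raw2[0, 10] = secs.cell_mean[0]
        secs2 = CorticalSections(raw2, np.ones_like(raw2), raw2.mean(axis=1) * 0 + secs.cell_mean,
                                 secs.unassigned_raw, secs.unassigned_counts)
        i2, _, _ = normalize_intensity(secs2)
        assert i2[0, 10] == pytest.approx(1.0)

    def test_affine_intensity_invariance(self):
        rng = np.random.default_rng(4)
        raw = rng.uniform(1.0, 4.0, (4, 100))
        a, b = normalize_intensity(sections_from_field(raw))[:2]
        a2, b2 = normalize_intensity(sections_from_field(3.5 * raw + 7.0))[:2]
        np.testing.assert_allclose(a, a2, atol=1e-10)
        np.testing.assert_allclose(b, b2, atol=1e-10)

    def test_flat_cell_flagged(self):
        secs = self._sections(np.full((3, 100), 2.0))
        _, _, flat = normalize_intensity(secs)
        assert flat.all()

    def test_equal_counts_smoothing_is_window_mean(self):
        rng = np.random.default_rng(5)
        raw = rng.uniform(1, 2, (2, 100))
        secs = self._sections(raw)
        i_norm, i_prime, _ = normalize_intensity(secs, smoothing="printed")
        k = 40
        window = [(k - 2) % 100, (k - 1) % 100, k, (k + 1) % 100]
        assert i_prime[0, k] == pytest.approx(i_norm[0, window].mean())

    def test_symmetric_smoothing_option(self):
        rng = np.random.default_rng(6)
        raw = rng.uniform(1, 2, (2, 100))
        secs = self._sections(raw)
        i_norm, i_prime, _ = normalize_intensity(secs, smoothing="symmetric")
        k = 13
        window = [(k + o) % 100 for o in (-2, -1, 0, 1, 2)]
        assert i_prime[0, k] == pytest.approx(i_norm[0, window].mean())

    def test_unassigned_normalization(self):
        secs = self._sections(np.tile(np.linspace(1, 3, 100), (2, 1)))
        un = normalize_unassigned(secs)
        expected = (2.0 - 1.0) / (secs.cell_mean[0] - 1.0)
        assert un[0] == pytest.approx(expected)


class TestRegions:
    def test_partition_on_circle_moving_plus_x(self):
        pts = _circle(100, 6.0)
        reg = assign_regions(pts, np.array([1.0, 0.0]))
        assert len(reg.front) == 30 and len(reg.rear) == 30
        assert len(reg.side_left) == 20 and len(reg.side_right) == 20
        union = np.concatenate([reg.front, reg.rear, reg.side_left, reg.side_right])
        assert len(np.unique(union)) == 100
        theta = np.arctan2(pts[:, 1], pts[:, 0])
        rear_center = theta[reg.rear[len(reg.rear) // 2]]
        front_center = theta[reg.front[len(reg.front) // 2]]
        assert abs(abs(rear_center) - np.pi) < 0.2
        assert abs(front_center) < 0.2
        # a radius-6 circle spans ~2*6*sin(0.3π) perpendicular to the motion
        assert reg.front_width == pytest.approx(2 * 6 * np.sin(0.3 * np.pi), rel=0.05)

    def test_undefined_direction_flagged(self):
        reg = assign_regions(_circle(100, 6.0), np.array([0.0, 0.0]))
        assert not reg.defined

    def test_rear_pool_rear_exceeds_front(self, quiet_cell):
        params, series, intensity, truth = quiet_cell
        secs = sections_from_field(intensity.boundary_values)
        i_norm, _, _ = normalize_intensity(secs)
        from protrudyn.migration import migration_direction

        dirs = migration_direction(truth.centroid_path)
        for t in range(params.n_frames - 2):
            reg = assign_regions(series.points[t], dirs[t])
            lv = region_levels(i_norm[t], secs.counts[t], reg)
            assert lv["rear"] > lv["front"]


def test_compute_kinematics_shapes(bump_cell):
    _, series, _, _ = bump_cell
    kin = compute_kinematics(series.points[:4])
    assert kin.curvature.shape == (4, 100)
    assert kin.shifts.shape == (3,)
    assert kin.motion.shape == (3, 100)
    assert kin.area_change.shape == (3, 100)
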