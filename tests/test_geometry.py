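"""Geometric angle-parameter extraction against closed-form references."""

import math

import numpy as np
import pytest

from acangle.geometry import (
    AOD_OFFSET_750,
    BScanSection,
    DegenerateAngleRegionError,
    InsufficientWallExtentError,
    IrisNotIntersectedError,
    LidUndefinedError,
    SpurOffWallError,
    compute_aod,
    compute_lid,
    compute_tisa750,
    find_endothelial_apex,
    measure_section,
    polyline_arclength,
    resample_polyline,
    wall_point_at_offset,
)

from oracles import ArcScene, phi_of_depth, random_scene, wall_xy


def _rigid(points, angle, shift):
    c, s = math.cos(angle), math.sin(angle)
    Rm = np.array([[c, -s], [s, c]])
    return np.asarray(points) @ Rm.T + np.asarray(shift)


def _arc_scene(R=6.5, y_spur=2.9, tent=True, bombe=1.0):
    phi_s = phi_of_depth(y_spur, R)
    phi_root = phi_s + 0.3 / R
    root = wall_xy(phi_root, R)
    p0 = np.array([1.6, root[1] - 0.45])
    if tent:
        summit = p0 + 0.5 * (root - p0) - np.array([0.0, bombe])
        iris = np.array([p0, summit, root])
    else:
        iris = np.array([p0, root])
    return ArcScene(R=R, phi_spur=phi_s, iris=iris,
                    phi_max=min(phi_root + 0.5 / R, 0.98 * math.pi / 2))


# ---------------------------------------------------------------------------
# wall_point_at_offset
# ---------------------------------------------------------------------------

class TestWallPointAtOffset:
    def test_straight_wall_offset_is_lateral_shift(self, parallel_plate):
        pt, tangent = wall_point_at_offset(parallel_plate, 0.75)
        assert pt == pytest.approx([-0.75, 0.0], abs=1e-12)
        assert abs(tangent[0]) == pytest.approx(1.0, abs=1e-12)

    def test_zero_offset_returns_snapped_spur(self, parallel_plate):
        pt, _ = wall_point_at_offset(parallel_plate, 0.0)
        assert pt == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_arc_offset_matches_dense_resampling(self):
        # circular wall of radius 6: the point 0.75 anterior to the spur sits
        # at central angle 0.75/6 rad before it; cross-checked against a
        # polyline resampled 20x denser
        scene = _arc_scene(R=6.0)
        sec = scene.build_section(spacing=0.004)
        pt, _ = wall_point_at_offset(sec, 0.75)
        exact = wall_xy(scene.phi_spur - 0.75 / 6.0, 6.0)
        assert np.linalg.norm(pt - exact) < 1e-3

        dense = BScanSection(
            posterior_cornea=resample_polyline(sec.posterior_cornea, 0.0002),
            anterior_iris=sec.anterior_iris,
            scleral_spur=sec.scleral_spur, side="right")
        pt_dense, _ = wall_point_at_offset(dense, 0.75)
        assert np.linalg.norm(pt - pt_dense) < 1e-3

    def test_insufficient_wall_extent(self, parallel_plate):
        with pytest.raises(InsufficientWallExtentError):
            wall_point_at_offset(parallel_plate, 10.0)

    def test_spur_off_wall_rejected_at_construction(self):
        wall = np.column_stack([np.linspace(-1, 1, 21), np.zeros(21)])
        iris = np.column_stack([np.linspace(-1, 1, 21), np.full(21, 0.2)])
        with pytest.raises(SpurOffWallError):
            BScanSection(posterior_cornea=wall, anterior_iris=iris,
                         scleral_spur=np.array([0.0, 0.2]), side="right")


# ---------------------------------------------------------------------------
# compute_aod
# ---------------------------------------------------------------------------

class TestComputeAOD:
    @pytest.mark.parametrize("offset", [0.0, 0.3, 0.75])
    def test_parallel_plates_give_constant_aod(self, parallel_plate, offset):
        assert compute_aod(parallel_plate, offset) == pytest.approx(0.2, abs=1e-9)

    def test_wedge_matches_analytic_line_heights(self, wedge):
        # iris y = 0.15 - 0.1 x above a flat wall: the vertical cast at the
        # spur reads 0.15 and at 750 um anterior (x = -0.75) reads 0.225
        assert compute_aod(wedge, 0.0) == pytest.approx(0.15, abs=1e-9)
        assert compute_aod(wedge, 0.75) == pytest.approx(0.225, abs=1e-9)

    def test_appositional_iris_reads_zero(self):
        wall = np.column_stack([np.linspace(-3.0, 1.2, 85), np.zeros(85)])
        iris = np.column_stack([np.linspace(-2.0, 0.5, 51), np.zeros(51)])
        sec = BScanSection(posterior_cornea=wall, anterior_iris=iris,
                           scleral_spur=np.array([0.0, 0.0]), side="right")
        assert compute_aod(sec, 0.0) == 0.0
        assert compute_aod(sec, 0.75) == 0.0

    def test_short_iris_raises(self, parallel_plate):
        sec = BScanSection(
            posterior_cornea=parallel_plate.posterior_cornea,
            anterior_iris=np.array([[0.6, 0.2], [1.0, 0.2]]),
            scleral_spur=np.array([0.0, 0.0]), side="right")
        with pytest.raises(IrisNotIntersectedError):
            compute_aod(sec, 0.75)

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scene = _arc_scene()
        sec = scene.build_section()
        ref = [compute_aod(sec, 0.0), compute_aod(sec, 0.75)]
        angle = rng.uniform(-0.4, 0.4)
        shift = rng.uniform(-3, 3, size=2)
        moved = BScanSection(
            posterior_cornea=_rigid(sec.posterior_cornea, angle, shift),
            anterior_iris=_rigid(sec.anterior_iris, angle, shift),
            scleral_spur=_rigid(sec.scleral_spur, angle, shift),
            side="right")
        assert compute_aod(moved, 0.0) == pytest.approx(ref[0], abs=1e-6)
        assert compute_aod(moved, 0.75) == pytest.approx(ref[1], abs=1e-6)


# ---------------------------------------------------------------------------
# compute_tisa750
# ---------------------------------------------------------------------------

class TestComputeTISA:
    def test_parallel_plates_rectangle(self, parallel_plate):
        assert compute_tisa750(parallel_plate) == pytest.approx(0.15, abs=1e-9)

    def test_wedge_trapezoid(self, wedge):
        expected = 0.5 * (0.15 + 0.225) * 0.75
        assert compute_tisa750(wedge) == pytest.approx(expected, abs=1e-9)

    def test_closed_angle_zero_area(self):
        wall = np.column_stack([np.linspace(-3.0, 1.2, 85), np.zeros(85)])
        iris = np.column_stack([np.linspace(-2.0, 0.5, 51), np.zeros(51)])
        sec = BScanSection(posterior_cornea=wall, anterior_iris=iris,
                           scleral_spur=np.array([0.0, 0.0]), side="right")
        assert compute_tisa750(sec) == 0.0

    def test_area_equals_integral_of_aod_for_straight_wall(self, wedge):
        offsets = np.linspace(0.0, AOD_OFFSET_750, 151)
        aods = [compute_aod(wedge, o) for o in offsets]
        integral = np.trapezoid(aods, offsets)
        assert compute_tisa750(wedge) == pytest.approx(integral, rel=0.01)

    def test_crossing_boundaries_degenerate(self):
        wall = np.column_stack([np.linspace(-3.0, 1.2, 85), np.zeros(85)])
        iris = np.array([[-2.0, 0.3], [-0.4, -0.05], [0.1, 0.25]])
        sec = BScanSection(posterior_cornea=wall, anterior_iris=iris,
                           scleral_spur=np.array([0.0, 0.0]), side="right")
        with pytest.raises(DegenerateAngleRegionError):
            compute_tisa750(sec)


# ---------------------------------------------------------------------------
# find_endothelial_apex
# ---------------------------------------------------------------------------

class TestFindApex:
    def test_circular_arc_minimum(self):
        phi = np.linspace(-0.35, 0.35, 701)
        arc = np.column_stack([6.5 * np.sin(phi), 6.5 * (1 - np.cos(phi))])
        assert find_endothelial_apex(arc) == pytest.approx([0.0, 0.0],
                                                           abs=1e-9)

    def test_noisy_arc_apex_near_true_minimum(self):
        rng = np.random.default_rng(42)
        phi = np.linspace(-0.25, 0.25, 3251)   # ~1 um lateral sampling
        arc = np.column_stack([6.5 * np.sin(phi), 6.5 * (1 - np.cos(phi))])
        arc[:, 1] += rng.normal(0.0, 0.005, len(arc))
        apex = find_endothelial_apex(arc)
        # the sagitta exceeds the noise beyond ~sqrt(2 R * few sigma)
        assert abs(apex[0]) < 0.6

    def test_tilted_arc_matches_analytic_rotation(self):
        phi = np.linspace(-0.5, 0.5, 2001)
        arc = np.column_stack([6.5 * np.sin(phi), 6.5 * (1 - np.cos(phi))])
        angle = 0.077  # ~0.5 mm decentration at the corneal radius
        tilted = _rigid(arc, angle, [0.0, 0.0])
        apex = find_endothelial_apex(tilted)
        centre = _rigid(np.array([[0.0, 6.5]]), angle, [0.0, 0.0])[0]
        expected = centre + np.array([0.0, -6.5])
        assert np.linalg.norm(apex - expected) < 2e-3

    def test_empty_polyline(self):
        with pytest.raises(ValueError, match="no boundary"):
            find_endothelial_apex(np.empty((0, 2)))


# ---------------------------------------------------------------------------
# compute_lid
# ---------------------------------------------------------------------------

class TestComputeLID:
    def test_supporting_ray_through_spur_gives_zero(self):
        # tent summit placed on the apex-spur chord: the grazing ray passes
        # through the spur exactly, the sign boundary
        R = 6.5
        phi_s = phi_of_depth(2.9, R)
        spur = wall_xy(phi_s, R)
        summit = 0.55 * spur
        phi_root = phi_s + 0.3 / R
        root = wall_xy(phi_root, R)
        iris = np.array([[1.5, summit[1] + 0.45], summit, root])
        scene = ArcScene(R=R, phi_spur=phi_s, iris=iris,
                         phi_max=phi_root + 0.5 / R)
        sec = scene.build_section()
        assert abs(compute_lid(sec, [0.0, 0.0])) < 1e-4

    def test_closed_form_line_circle_intersection(self):
        scene = _arc_scene()
        sec = scene.build_section()
        assert compute_lid(sec, [0.0, 0.0]) == pytest.approx(scene.lid(),
                                                             abs=1e-3)

    def test_anterior_iris_translation_decreases_lid(self):
        # raising the iris (smaller anterior chamber depth) must drive LID
        # monotonically toward more negative values
        base = _arc_scene()
        lids = []
        for dy in np.linspace(0.0, 0.5, 6):
            iris = base.iris.copy()
            iris[:2, 1] -= dy          # root stays on the wall
            scene = ArcScene(R=base.R, phi_spur=base.phi_spur, iris=iris,
                             phi_max=base.phi_max)
            lids.append(compute_lid(scene.build_section(), [0.0, 0.0]))
        assert np.all(np.diff(lids) < 0)

    def test_posterior_translation_flips_sign_continuously(self):
        base = _arc_scene()
        dys = np.linspace(-0.30, 0.05, 15)
        lids = []
        for dy in dys:
            iris = base.iris.copy()
            iris[:2, 1] += dy
            scene = ArcScene(R=base.R, phi_spur=base.phi_spur, iris=iris,
                             phi_max=base.phi_max)
            lids.append(compute_lid(scene.build_section(), [0.0, 0.0]))
        lids = np.array(lids)
        assert lids[0] < 0 < lids[-1]
        assert np.all(np.diff(lids) > 0)
        assert np.max(np.abs(np.diff(lids))) < 0.15  # no jumps through zero

    def test_wide_open_ray_reports_missing(self, parallel_plate):
        with pytest.raises(LidUndefinedError):
            compute_lid(parallel_plate, [-3.0, 0.0])

    def test_arc_distance_option(self):
        scene = _arc_scene()
        sec = scene.build_section()
        euclid = compute_lid(sec, [0.0, 0.0], distance="euclidean")
        arc = compute_lid(sec, [0.0, 0.0], distance="arc")
        assert math.copysign(1, euclid) == math.copysign(1, arc)
        assert abs(arc) >= abs(euclid) - 1e-9   # chord never exceeds arc


# ---------------------------------------------------------------------------
# oracle equivalence and resolution stability
# ---------------------------------------------------------------------------

class TestOracleEquivalence:
    @pytest.mark.parametrize("seed,tent", [(s, s % 3 != 0) for s in range(20)])
    def test_random_scene_metrics_match_closed_forms(self, seed, tent):
        rng = np.random.default_rng(1000 + seed)
        scene = random_scene(rng, tent=tent)
        sec = scene.build_section()
        m = measure_section(sec, [0.0, 0.0])
        assert m.failures == {}
        assert m.aodss == pytest.approx(scene.aod(0.0)[0], abs=1e-3)
        assert m.aod750 == pytest.approx(scene.aod(0.75)[0], abs=1e-3)
        assert m.tisa750 == pytest.approx(scene.tisa750(), abs=1e-4)
        assert m.lid == pytest.approx(scene.lid(), abs=1e-3)

    @pytest.mark.parametrize("seed", range(6))
    def test_double_density_stability(self, seed):
        rng = np.random.default_rng(2000 + seed)
        scene = random_scene(rng, tent=True)
        m1 = measure_section(scene.build_section(0.004), [0.0, 0.0])
        m2 = measure_section(scene.build_section(0.002), [0.0, 0.0])
        for name in ("aodss", "aod750", "lid"):
            assert abs(getattr(m1, name) - getattr(m2, name)) < 1e-3
        assert abs(m1.tisa750 - m2.tisa750) < 1e-4


# ---------------------------------------------------------------------------
# measure_section
# ---------------------------------------------------------------------------

class TestMeasureSection:
    def test_wedge_composition(self, wedge):
        m = measure_section(wedge, [-3.0, 0.0])
        assert m.aodss == pytest.approx(0.15, abs=1e-9)
        assert m.aod750 == pytest.approx(0.225, abs=1e-9)
        assert m.tisa750 == pytest.approx(0.140625, abs=1e-9)
        # straight scene: the grazing ray never returns to the wall, so LID
        # is missing with a reason rather than clamped
        assert m.lid is None
        assert "lid" in m.failures

    def test_appositional_section_reads_zero_not_missing(self):
        wall = np.column_stack([np.linspace(-3.0, 1.2, 85), np.zeros(85)])
        iris = np.column_stack([np.linspace(-2.0, 0.5, 51), np.zeros(51)])
        sec = BScanSection(posterior_cornea=wall, anterior_iris=iris,
                           scleral_spur=np.array([0.0, 0.0]), side="right")
        m = measure_section(sec, [-3.0, 0.0])
        assert (m.aodss, m.aod750, m.tisa750) == (0.0, 0.0, 0.0)
        assert "aodss" not in m.failures

    def test_failures_are_per_metric(self, parallel_plate):
        sec = BScanSection(
            posterior_cornea=parallel_plate.posterior_cornea,
            anterior_iris=np.array([[-0.5, 0.2], [0.5, 0.2]]),
            scleral_spur=np.array([0.0, 0.0]), side="right")
        m = measure_section(sec, [-3.0, 0.0])
        assert m.aodss == pytest.approx(0.2, abs=1e-9)   # spur cast still hits
        assert m.aod750 is None and "aod750" in m.failures
        assert m.status() != "ok"


class TestSectionValidation:
    def test_requires_monotone_lateral_progression(self):
        wall = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 0.1]])
        iris = np.array([[0.0, 0.2], [1.0, 0.2]])
        with pytest.raises(ValueError, match="monotonically"):
            BScanSection(posterior_cornea=wall, anterior_iris=iris,
                         scleral_spur=np.array([0.0, 0.0]), side="right")

    def test_arclength_bookkeeping(self):
        poly = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 2.0]])
        assert polyline_arclength(poly) == pytest.approx([0.0, 1.0, 3.0])
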