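"""Circle fitting, contact angles and fluid-elastic wetting parameters."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import least_squares

from memwet.synthetic import simulate_wetting_geometry
from memwet.wetting import (
    ContactAngles,
    GeometryError,
    affinity_contrast,
    apparent_angles,
    fit_circle,
    geometric_factor,
    geometric_factor_from_intrinsic,
    intrinsic_angle,
    segment_tensions,
    tension_triangle_angles,
    validate_geometry,
    wetting_parameters,
)


def circle_points(center, radius, n=100, span=(0, 2 * math.pi), rng=None, noise=0.0):
    t = np.linspace(*span, n)
    pts = np.column_stack([center[0] + radius * np.cos(t),
                           center[1] + radius * np.sin(t)])
    if noise > 0:
        pts += rng.normal(0, noise, pts.shape)
    return pts


def geometric_circle_refit(points):
    """Independent nonlinear (Levenberg-style) geometric circle fit."""
    x, y = points.T
    cx0, cy0 = x.mean(), y.mean()
    r0 = np.hypot(x - cx0, y - cy0).mean()

    def resid(p):
        return np.hypot(x - p[0], y - p[1]) - p[2]

    sol = least_squares(resid, [cx0, cy0, r0], method="lm")
    return sol.x


class TestFitCircle:
    def test_exact_points_recover_circle_exactly(self):
        model = fit_circle(circle_points((0, 0), 5.0, n=100))
        assert model.center == pytest.approx((0, 0), abs=1e-9)
        assert model.radius == pytest.approx(5.0, abs=1e-9)
        assert model.rms_residual < 1e-9
        assert not model.is_line

    def test_three_point_circumcircle(self):
        model = fit_circle(np.array([[0.0, 1.0], [1.0, 0.0], [0.0, -1.0]]))
        assert model.center == pytest.approx((0, 0), abs=1e-9)
        assert model.radius == pytest.approx(1.0, abs=1e-9)

    def test_noisy_arc_matches_geometric_refit_oracle(self, rng):
        pts = circle_points((2, -3), 8.0, n=200, span=(0.3, 2.5), rng=rng,
                            noise=0.08)  # sigma = 0.01 R
        model = fit_circle(pts)
        cx, cy, r = geometric_circle_refit(pts)
        assert model.radius == pytest.approx(8.0, rel=0.01)
        assert model.radius == pytest.approx(r, rel=0.005)
        assert model.center == pytest.approx((cx, cy), abs=0.05)

    def test_collinear_points_fall_back_to_line(self):
        t = np.linspace(0, 10, 50)
        pts = np.column_stack([t, 0.5 * t + 1.0])
        model = fit_circle(pts)
        assert model.is_line
        d = np.asarray(model.line_dir)
        assert abs(d @ np.array([1, 0.5]) / np.hypot(1, 0.5)) == pytest.approx(1.0, abs=1e-9)
        assert model.rms_residual < 1e-9

    def test_collinear_without_fallback_raises(self):
        pts = np.column_stack([np.linspace(0, 1, 10), np.zeros(10)])
        with pytest.raises(GeometryError, match="collinear"):
            fit_circle(pts, allow_line=False)

    def test_too_few_points_rejected(self):
        with pytest.raises(GeometryError):
            fit_circle(np.array([[0.0, 0.0], [1.0, 1.0]]))


def construct_and_invert(theta_i, theta_e, theta_c, **kwargs):
    """Forward-construct arcs with prescribed angles, then measure them back.

    The tension triple realising the angles follows from the law of sines
    (sigma_ce = 1), so the constructed geometry has the requested tangents.
    """
    si = math.sin(math.radians(theta_i))
    sigma_ie = math.sin(math.radians(theta_c)) / si
    sigma_ic = math.sin(math.radians(theta_e)) / si
    W = sigma_ic - sigma_ie
    sigma_mean = 0.5 * (sigma_ic + sigma_ie)
    contours, truth = simulate_wetting_geometry(1.0, W, sigma_mean, **kwargs)
    angles = apparent_angles(fit_circle(contours.arc_ie), fit_circle(contours.arc_ic),
                             fit_circle(contours.arc_ce))
    return angles, truth


class TestApparentAngles:
    def test_symmetric_geometry_recovers_120_degrees(self):
        angles, _ = construct_and_invert(120.0, 120.0, 120.0)
        assert angles.as_tuple() == pytest.approx((120, 120, 120), abs=0.1)
        assert angles.asymmetry_deg < 1e-6

    def test_prescribed_asymmetric_angles_recovered(self):
        angles, truth = construct_and_invert(150.0, 90.0, 120.0)
        assert angles.theta_i == pytest.approx(150.0, abs=0.1)
        assert angles.theta_e == pytest.approx(90.0, abs=0.1)
        assert angles.theta_c == pytest.approx(120.0, abs=0.1)

    def test_flat_ic_interface_same_inversion_contract(self):
        contours, truth = simulate_wetting_geometry(1.0, W=-0.2, sigma_mean=0.9,
                                                    flat_ic=True)
        cic = fit_circle(contours.arc_ic)
        assert cic.is_line
        angles = apparent_angles(fit_circle(contours.arc_ie), cic,
                                 fit_circle(contours.arc_ce))
        expected = (truth.params["theta_i"], truth.params["theta_e"],
                    truth.params["theta_c"])
        assert angles.as_tuple() == pytest.approx(expected, abs=0.1)

    def test_angle_sum_is_360_for_generated_geometry(self):
        angles, _ = construct_and_invert(140.0, 100.0, 120.0)
        assert angles.angle_sum == pytest.approx(360.0, abs=1e-6)

    def test_non_intersecting_circles_raise(self):
        far = fit_circle(circle_points((100, 100), 1.0))
        near = fit_circle(circle_points((0, 0), 5.0))
        with pytest.raises(GeometryError, match="no contact line"):
            apparent_angles(near, near, far)

    def test_inconsistent_third_arc_raises(self):
        c1 = fit_circle(circle_points((0, 0), 5.0))
        c2 = fit_circle(circle_points((4, 0), 5.0))
        stray = fit_circle(circle_points((2, 40), 3.0))  # misses contact points
        with pytest.raises(GeometryError, match="inconsistent"):
            apparent_angles(c1, stray, c2)


class TestFluidElasticParameters:
    def test_equal_external_and_condensate_angles_give_zero_phi(self):
        assert geometric_factor(ContactAngles(140, 110, 110)) == pytest.approx(0.0, abs=1e-15)

    def test_dewetting_limit_phi_is_plus_one(self):
        # theta_e_in = 0 at dewetting: the geometric factor reaches +1
        assert geometric_factor_from_intrinsic(0.0) == 1.0
        phi = geometric_factor(tension_triangle_angles(1.0, 1.0, 1.0 + (1 - 1e-9)))
        assert phi == pytest.approx(1.0, abs=1e-4)

    def test_complete_wetting_limit(self):
        assert geometric_factor_from_intrinsic(180.0) == -1.0
        assert intrinsic_angle(-1.0) == pytest.approx(180.0, abs=1e-12)

    def test_known_triple_evaluates_exactly(self):
        phi = geometric_factor(ContactAngles(150, 90, 120))
        expected = (1 - math.sin(math.radians(120))) / math.sin(math.radians(150))
        assert phi == pytest.approx(expected, abs=1e-15)
        assert phi == pytest.approx(0.26795, abs=1e-5)
        assert intrinsic_angle(phi) == pytest.approx(74.46, abs=0.01)

    def test_degenerate_theta_i_rejected(self):
        with pytest.raises(GeometryError):
            geometric_factor(ContactAngles(180.0 - 1e-14, 90.0, 90.0))

    def test_intrinsic_angle_clamps_tolerance_but_rejects_beyond(self):
        assert intrinsic_angle(0.0) == pytest.approx(90.0)
        assert intrinsic_angle(1.0 + 1e-10) == 0.0
        with pytest.raises(GeometryError):
            intrinsic_angle(1.1)

    def test_affinity_contrast_values(self):
        assert affinity_contrast(0.0, 20.0) == 0.0
        assert affinity_contrast(1.0, 15.7) == pytest.approx(15.7)
        assert affinity_contrast(-0.5, 10.0) == pytest.approx(-5.0)
        with pytest.raises(GeometryError):
            affinity_contrast(0.5, 0.0)

    def test_segment_tensions_equilateral_triangle(self):
        s_ie, s_ic = segment_tensions(ContactAngles(120, 120, 120), 1.0)
        assert (s_ie, s_ic) == pytest.approx((1.0, 1.0))

    def test_segment_tensions_known_triple(self):
        s_ie, s_ic = segment_tensions(ContactAngles(150, 90, 120), 15.7)
        assert s_ie == pytest.approx(27.19, abs=0.01)
        assert s_ic == pytest.approx(31.40, abs=0.01)

    def test_segment_tensions_scale_linearly_with_sigma_ce(self):
        angles = ContactAngles(150, 90, 120)
        a = segment_tensions(angles, 10.0)
        b = segment_tensions(angles, 20.0)
        assert b == pytest.approx(tuple(2 * x for x in a))

    def test_phi_monotone_in_angle_asymmetry_at_fixed_theta_i(self):
        # at fixed theta_i (valid triples keep theta_e + theta_c fixed), Phi is
        # strictly increasing in theta_c - theta_e: theta_c -> 0 at complete
        # wetting (Phi = -1) and theta_e -> 0 at dewetting (Phi = +1)
        for theta_i in (100.0, 140.0, 160.0):
            total = 360.0 - theta_i
            deltas = np.linspace(-min(total / 2, 180) + 1, min(total / 2, 180) - 1, 9)
            phis = [geometric_factor(ContactAngles(theta_i, total / 2 - d / 2,
                                                   total / 2 + d / 2))
                    for d in deltas]
            assert np.all(np.diff(phis) > 0)


tension_triples = st.tuples(
    st.floats(-0.9, 0.9),  # W / sigma_ce
    st.floats(0.7, 2.5),  # sigma_mean / sigma_ce
).filter(lambda t: abs(t[0]) < 2 * t[1] - 1e-6)


class TestTensionTriangle:
    @given(tension_triples)
    def test_round_trip_tensions_to_angles_to_phi(self, triple):
        W, sm = triple
        sigma_ce = 1.0
        angles = tension_triangle_angles(sigma_ce, sm - W / 2, sm + W / 2)
        assert angles.angle_sum == pytest.approx(360.0, abs=1e-9)
        phi = geometric_factor(angles)
        assert phi == pytest.approx(W / sigma_ce, abs=2e-9, rel=1e-9)
        assert phi == pytest.approx(
            geometric_factor_from_intrinsic(intrinsic_angle(phi)), abs=1e-12)

    @given(tension_triples)
    def test_law_of_sines_closure(self, triple):
        W, sm = triple
        angles = tension_triangle_angles(1.0, sm - W / 2, sm + W / 2)
        s_ie, s_ic = segment_tensions(angles, 1.0)
        assert s_ie == pytest.approx(sm - W / 2, rel=1e-9, abs=1e-9)
        assert s_ic == pytest.approx(sm + W / 2, rel=1e-9, abs=1e-9)

    def test_triangle_inequality_violation_rejected(self):
        with pytest.raises(GeometryError, match="triangle"):
            tension_triangle_angles(1.0, 0.2, 2.0)


class TestValidateGeometry:
    def test_closed_triangle_passes_all_checks(self):
        angles = tension_triangle_angles(1.0, 1.2, 1.5)
        report = validate_geometry(angles)
        assert report.ok
        assert report.closure_residual < 1e-9

    def test_wrong_angle_sum_flagged(self):
        report = validate_geometry(ContactAngles(100, 100, 100))
        assert not report.angle_sum_ok
        assert report.angle_sum_deviation_deg == pytest.approx(-60.0)
        assert any("angle sum" in f for f in report.flags)

    def test_noise_perturbation_reported_not_fatal(self, rng):
        angles = tension_triangle_angles(1.0, 1.2, 1.5)
        devs = []
        for _ in range(200):
            noisy = ContactAngles(*(t + rng.normal(0, 1.0) for t in angles.as_tuple()))
            report = validate_geometry(noisy)  # must not raise
            devs.append(abs(report.angle_sum_deviation_deg))
        assert np.mean(devs) < 3 * 1.0 * math.sqrt(3)  # bounded by noise scale


class TestPipelineRecovery:
    def test_phi_recovered_from_noisy_rendered_contours(self):
        rng = np.random.default_rng(202)
        for k in range(25):
            W = rng.uniform(-0.8, 0.8)
            sm = rng.uniform(0.8, 1.8)
            contours, truth = simulate_wetting_geometry(
                1.0, W, sm, noise_sigma=0.5, pixel_size=0.1, seed=int(rng.integers(2**31)))
            angles = apparent_angles(fit_circle(contours.arc_ie),
                                     fit_circle(contours.arc_ic),
                                     fit_circle(contours.arc_ce))
            assert geometric_factor(angles) == pytest.approx(truth.params["phi"], abs=0.05)

    def test_wetting_parameters_bundle_consistent(self):
        angles = ContactAngles(150, 90, 120)
        wg = wetting_parameters(angles, 15.7)
        assert wg.affinity_contrast == pytest.approx(wg.phi * 15.7)
        assert wg.phi == pytest.approx(math.cos(math.radians(wg.theta_e_in)), abs=1e-12)
        assert -15.7 <= wg.affinity_contrast <= 15.7
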