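"""Closed-form solver vs forward oracle and a brute-force hyperbola solver."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import least_squares

from coopssl.geometry import (
    FARFIELD,
    DegenerateSourceError,
    InfeasibleTdoaError,
    MicArrayGeometry,
    TdoaMeasurement,
    axis_to_boresight,
    forward_delays,
    solve_angle,
    solve_fix,
    solve_range,
)


def polar_source(r, phi_deg):
    """Source position from range (from S2) and boresight angle."""
    return (r * math.sin(math.radians(phi_deg)),
            r * math.cos(math.radians(phi_deg)))


def brute_force_fix(tdoa, geometry):
    """Independent oracle: numerically intersect the two TDOA hyperbolas.

    Solves for (x, y) such that r1-r2 = c*t12 and r2-r3 = c*t23 with the
    microphones at (-a, 0), (0, 0), (b, 0); returns (r2, theta_deg).
    """
    a, b, c = geometry.a, geometry.b, geometry.c

    def residuals(p):
        x, y = p
        r1 = math.hypot(x + a, y)
        r2 = math.hypot(x, y)
        r3 = math.hypot(x - b, y)
        return [r1 - r2 - c * tdoa.t12, r2 - r3 - c * tdoa.t23]

    sol = least_squares(residuals, x0=[0.0, 1.0], xtol=1e-15, ftol=1e-15,
                        gtol=1e-15)
    x, y = sol.x
    r2 = math.hypot(x, y)
    return r2, math.degrees(math.atan2(abs(y), x))


class TestForwardDelays:
    def test_mirror_symmetry_broadside(self):
        geom = MicArrayGeometry(mic_positions=(0.0, 0.1, 0.2, 0.3),
                                solver_triple=(0, 1, 2))
        td = forward_delays(geom, (0.0, 1.0))
        assert td.t23 == pytest.approx(-td.t12, abs=1e-15)

    def test_direct_evaluation(self, geometry):
        td = forward_delays(geometry, (0.5, 1.2))
        r1 = math.hypot(0.649, 1.2)
        assert td.t12 == pytest.approx((r1 - 1.3) / 340.0, rel=1e-12)

    def test_endfire_source_delays_equal_spacings(self, geometry):
        td = forward_delays(geometry, (1.0, 0.0))
        assert td.t12 == pytest.approx(geometry.a / 340.0, rel=1e-12)
        assert td.t23 == pytest.approx(geometry.b / 340.0, rel=1e-12)

    def test_source_at_microphone_is_degenerate(self, geometry):
        with pytest.raises(DegenerateSourceError):
            forward_delays(geometry, (0.0, 0.0))


class TestSolveRangeAngle:
    def test_round_trip_known_point(self, geometry):
        td = forward_delays(geometry, (0.5, 1.2))
        assert solve_range(td, geometry) == pytest.approx(1.3, rel=1e-9)
        theta = solve_angle(td, geometry)
        assert theta == pytest.approx(math.degrees(math.acos(0.5 / 1.3)),
                                      abs=1e-9)
        assert axis_to_boresight(theta) == pytest.approx(22.62, abs=0.01)

    def test_zero_delays_are_farfield(self, geometry):
        assert solve_range(TdoaMeasurement(0.0, 0.0), geometry) is FARFIELD

    def test_infeasible_delay_raises(self, geometry):
        bad = TdoaMeasurement(t12=2 * geometry.a / geometry.c, t23=0.0)
        with pytest.raises(InfeasibleTdoaError):
            solve_range(bad, geometry)

    def test_broadside_symmetric_geometry_gives_phi_zero(self):
        geom = MicArrayGeometry(mic_positions=(0.0, 0.1, 0.2, 0.3),
                                solver_triple=(0, 1, 2))
        t = 2e-5  # |c t| = 6.8 mm < 100 mm spacing
        theta = solve_angle(TdoaMeasurement(t12=t, t23=-t), geom)
        assert theta == pytest.approx(90.0, abs=1e-9)
        assert axis_to_boresight(theta) == pytest.approx(0.0, abs=1e-9)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(r=st.floats(0.3, 3.0), theta=st.floats(5.0, 175.0))
    def test_round_trip_recovers_range_and_angle(self, geometry, r, theta):
        src = polar_source(r, 90.0 - theta)
        td = forward_delays(geometry, src)
        assert solve_range(td, geometry) == pytest.approx(r, rel=1e-6)
        assert solve_angle(td, geometry) == pytest.approx(theta, rel=1e-6)

    def test_mirror_sources_identical_fix(self, geometry, rng):
        for _ in range(20):
            x = rng.uniform(-1, 1)
            y = rng.uniform(0.3, 2.0)
            up, down = forward_delays(geometry, (x, y)), forward_delays(
                geometry, (x, -y))
            assert up == down
            assert solve_fix(up, geometry) == solve_fix(down, geometry)

    def test_matches_brute_force_hyperbola_intersection(self, geometry, rng):
        for _ in range(200):
            r = rng.uniform(0.3, 3.0)
            phi = rng.uniform(-60.0, 60.0)
            td = forward_delays(geometry, polar_source(r, phi))
            r2_bf, theta_bf = brute_force_fix(td, geometry)
            assert solve_range(td, geometry) == pytest.approx(r2_bf, abs=1e-6)
            assert solve_angle(td, geometry) == pytest.approx(theta_bf,
                                                              abs=1e-6)

    def test_farfield_limit_angle_converges(self, geometry):
        phi = 20.0
        for r in (10.0, 100.0, 1000.0):
            td = forward_delays(geometry, polar_source(r, phi))
            err = abs(axis_to_boresight(solve_angle(td, geometry)) - phi)
            assert err < 1e-6
        # and at a genuinely planar wavefront the range is unresolvable
        t12 = geometry.a * math.sin(math.radians(phi)) / geometry.c
        t23 = geometry.b * math.sin(math.radians(phi)) / geometry.c
        assert solve_range(TdoaMeasurement(t12, t23), geometry) is FARFIELD


class TestConventions:
    @pytest.mark.parametrize(
        "theta,phi", [(90.0, 0.0), (67.38, 22.62), (120.0, -30.0)]
    )
    def test_axis_to_boresight(self, theta, phi):
        assert axis_to_boresight(theta) == pytest.approx(phi)

    def test_axis_angle_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            axis_to_boresight(181.0)

    def test_default_geometry_spacings(self, geometry):
        gaps = np.diff(geometry.mic_positions)
        assert gaps == pytest.approx([0.149, 0.040, 0.037])
        assert geometry.a == pytest.approx(0.149)
        assert geometry.b == pytest.approx(0.077)

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            MicArrayGeometry(mic_positions=(0.0, 0.0, 0.1, 0.2))
        with pytest.raises(ValueError):
            MicArrayGeometry(solver_triple=(0, 2, 1))
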