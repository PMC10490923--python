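"""Refraction model: Snell's law, transfer constants, apparent distance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluolevel.optics import (
    DEFAULT_THETA1,
    OpticalStack,
    TotalInternalReflection,
    apparent_distance,
    apparent_perimeter,
    fill_stack,
    snell_refract,
    trace_ray_oracle,
    transfer_constants,
)

WATER = 1.333


@pytest.mark.parametrize(
    "theta_in, n_in, n_out, expected_deg",
    [
        (0.0, 1.0, 1.333, 0.0),  # normal incidence is unrefracted
        (math.radians(25.0), 1.2, 1.2, 25.0),  # identical media
        (math.radians(30.0), 1.0, 1.5, 19.47122063449069),  # arcsin(sin30/1.5)
    ],
)
def test_snell_refract_known_angles(theta_in, n_in, n_out, expected_deg):
    assert math.degrees(snell_refract(theta_in, n_in, n_out)) == pytest.approx(
        expected_deg, abs=1e-12
    )


def test_snell_total_internal_reflection():
    # Dense-to-rare beyond the critical angle (arcsin(1/1.5) ~ 41.8 deg).
    with pytest.raises(TotalInternalReflection):
        snell_refract(math.radians(60.0), 1.5, 1.0)
    # Just below the critical angle still refracts.
    out = snell_refract(math.radians(41.0), 1.5, 1.0)
    assert 0 < out < math.pi / 2


def test_snell_rejects_bad_domain():
    with pytest.raises(ValueError):
        snell_refract(math.pi / 2, 1.0, 1.333)
    with pytest.raises(ValueError):
        snell_refract(0.1, 0.5, 1.0)


@given(
    theta=st.floats(0.0, math.radians(80.0)),
    n1=st.floats(1.0, 2.0),
    n2=st.floats(1.0, 2.0),
)
@settings(max_examples=200, deadline=None)
def test_snell_is_reversible(theta, n1, n2):
    """Refracting into a medium and back recovers the incidence angle."""
    try:
        mid = snell_refract(theta, n1, n2)
        back = snell_refract(mid, n2, n1)
    except TotalInternalReflection:
        return
    assert back == pytest.approx(theta, abs=1e-12)


class TestTransferConstants:
    def test_matched_indices_collapse(self):
        stack = OpticalStack(n_outer=1.2, n_fluid=1.2, h0=40, h1=5, L=10)
        c = transfer_constants(stack, math.radians(20))
        assert c.C1 == pytest.approx(c.C2)

    def test_tan_45_is_unity(self):
        stack = OpticalStack(n_outer=1.0, n_fluid=WATER, h0=40, h1=5, L=10)
        c = transfer_constants(stack, math.radians(45))
        assert c.C1 == pytest.approx(1.0)
        assert c.C0 == pytest.approx(stack.h - stack.h1)

    def test_water_at_30_degrees(self):
        stack = OpticalStack(n_outer=1.0, n_fluid=WATER, h0=40, h1=5, L=10)
        c = transfer_constants(stack, math.radians(30))
        assert c.C2 == pytest.approx(math.tan(math.asin(0.5 / WATER)), rel=1e-12)
        assert c.C2 < c.C1  # denser fluid bends the ray toward the normal

    @pytest.mark.parametrize("theta", [0.0, math.pi / 2, -0.1])
    def test_rejects_out_of_range_angle(self, theta):
        stack = OpticalStack(n_outer=1.0, n_fluid=WATER, h0=40, h1=5, L=10)
        with pytest.raises(ValueError):
            transfer_constants(stack, theta)


class TestApparentDistance:
    def test_no_fluid_gives_true_distance(self):
        stack = OpticalStack(n_outer=1.0, n_fluid=WATER, h0=50, h1=5, L=0)
        assert apparent_distance(stack) == pytest.approx(stack.h, rel=1e-12)

    def test_matched_indices_give_true_distance(self):
        stack = OpticalStack(n_outer=1.3, n_fluid=1.3, h0=50, h1=5, L=17)
        assert apparent_distance(stack, math.radians(12)) == pytest.approx(stack.h, rel=1e-12)

    def test_matches_ray_trace_oracle_on_grid(self):
        """Closed form vs. brute-force back-projection, < 1e-9 relative."""
        for L in np.linspace(0.0, 25.0, 10):
            for theta1 in np.radians([1, 5, 15, 30, 45]):
                for n_fluid in (1.0, 1.333, 1.5, 1.8):
                    stack = OpticalStack(1.0, n_fluid, h0=50, h1=5, L=float(L))
                    closed = apparent_distance(stack, theta1)
                    traced = trace_ray_oracle(stack, theta1).apparent_distance
                    assert closed == pytest.approx(traced, rel=1e-9)

    def test_first_degree_in_depth(self):
        """An L-sweep lies exactly on a line (fixed h0, h1, theta1)."""
        L = np.arange(0.0, 21.0, 2.0)
        I = np.array(
            [
                apparent_distance(OpticalStack(1.0, WATER, 50, 5, float(x)), math.radians(10))
                for x in L
            ]
        )
        coeffs = np.polyfit(L, I, 1)
        residual = I - np.polyval(coeffs, L)
        assert np.max(np.abs(residual)) / np.max(np.abs(I)) < 1e-9

    def test_filling_well_appears_closer(self):
        """Fixed well filling with water: I strictly decreasing in depth."""
        depths = np.linspace(0.0, 20.0, 11)
        I = [apparent_distance(fill_stack(65.0, 5.0, float(L))) for L in depths]
        assert all(b < a for a, b in zip(I, I[1:]))

    def test_rare_fluid_inverts_relationship(self):
        """Fluid less dense than the surroundings pushes the image away."""
        depths = np.linspace(0.0, 20.0, 11)
        I = [
            apparent_distance(fill_stack(65.0, 5.0, float(L), n_outer=1.333, n_fluid=1.0))
            for L in depths
        ]
        assert all(b > a for a, b in zip(I, I[1:]))

    def test_paraxial_limit_is_apparent_depth_formula(self):
        """theta1 -> 0 recovers the classical h0 + h1 + L*n_outer/n_fluid."""
        stack = OpticalStack(1.0, WATER, h0=50, h1=5, L=10)
        expected = stack.h0 + stack.h1 + stack.L * stack.n_outer / stack.n_fluid
        got = apparent_distance(stack, math.radians(0.1))
        assert got == pytest.approx(expected, rel=1e-4)
        # and the deviation shrinks as the angle does
        closer = apparent_distance(stack, math.radians(0.01))
        assert abs(closer - expected) < abs(got - expected)


class TestRayTraceOracle:
    @given(
        L=st.floats(0.0, 30.0),
        theta1=st.floats(0.01, math.radians(60.0)),
        n_fluid=st.floats(1.0, 1.8),
    )
    @settings(max_examples=100, deadline=None)
    def test_exit_angle_equals_incidence(self, L, theta1, n_fluid):
        """Parallel interfaces return the ray to its original angle."""
        stack = OpticalStack(1.0, n_fluid, h0=50, h1=5, L=L)
        result = trace_ray_oracle(stack, theta1)
        assert result.exit_angle == pytest.approx(theta1, abs=1e-12)

    def test_oracle_sweep_is_linear(self):
        """Oracle self-consistency with the stated first-degree behavior."""
        L = np.arange(0.0, 21.0, 2.0)
        I = np.array(
            [
                trace_ray_oracle(
                    OpticalStack(1.0, WATER, 50, 5, float(x)), math.radians(20)
                ).apparent_distance
                for x in L
            ]
        )
        coeffs = np.polyfit(L, I, 1)
        assert np.max(np.abs(I - np.polyval(coeffs, L))) / np.max(I) < 1e-9

    def test_zero_depth_recovers_geometry(self):
        stack = OpticalStack(1.0, WATER, h0=50, h1=5, L=0)
        assert trace_ray_oracle(stack).apparent_distance == pytest.approx(stack.h, rel=1e-12)


class TestApparentPerimeter:
    def test_inverse_proportionality(self):
        p1 = apparent_perimeter(30.0, 5.0, 1000.0)
        p2 = apparent_perimeter(60.0, 5.0, 1000.0)
        assert p2 == pytest.approx(p1 / 2)

    def test_units_identity(self):
        assert apparent_perimeter(1000.0, 1 / math.pi, 1000.0) == pytest.approx(1.0)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            apparent_perimeter(0.0, 5.0, 1000.0)

    def test_spot_grows_as_well_fills(self):
        """Composition with the fill sweep: perimeter monotone in volume."""
        depths = np.linspace(0.0, 20.0, 11)
        perims = [
            apparent_perimeter(apparent_distance(fill_stack(65.0, 5.0, float(L))), 5.0, 1500.0)
            for L in depths
        ]
        assert all(b > a for a, b in zip(perims, perims[1:]))


def test_stack_validation():
    with pytest.raises(ValueError):
        OpticalStack(0.9, WATER, 50, 5, 10)  # index below vacuum
    with pytest.raises(ValueError):
        OpticalStack(1.0, WATER, 0.0, 5, 10)  # source on the surface
    with pytest.raises(ValueError):
        OpticalStack(1.0, WATER, 50, -1, 10)
    s = OpticalStack(1.0, WATER, 50, 5, 10)
    assert s.h == pytest.approx(65.0)
    with pytest.raises(ValueError):
        fill_stack(20.0, 5.0, 18.0)  # fluid deeper than the column


def test_default_angle_is_small():
    assert 0 < DEFAULT_THETA1 < math.radians(10)
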