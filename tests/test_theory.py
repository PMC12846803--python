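"""Closed-form boundary-layer theory: effective Péclet number and
diffusivity, similarity solution, adhesion-rate laws, critical shear,
scaling collapse and regime classification."""

import dataclasses
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, optimize

from active_leveque import theory
from active_leveque.parameters import (
    BacteriumParams,
    DimensionlessGroups,
    ParameterError,
    dimensionless_groups,
)

betas = st.floats(0.0, 0.95)
pers = st.floats(0.05, 50.0)
vss = st.floats(1e-3, 0.5)


def groups_of(vs, per):
    return DimensionlessGroups(rel_swim_speed=vs, rot_peclet=per)


def quiet_peclet(vs, per, beta):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return theory.effective_peclet(groups_of(vs, per), beta)


class TestEffectivePeclet:
    @given(per=pers, vs=vss)
    def test_sphere_reduces_to_printed_form(self, per, vs):
        expected = (4.0 + per**2) / (2.0 * per * vs**2)
        assert quiet_peclet(vs, per, 0.0) == pytest.approx(expected, rel=1e-12)

    def test_reference_value(self):
        assert quiet_peclet(0.1, 2.0, 0.0) == pytest.approx(200.0, rel=1e-12)

    def test_weak_flow_limit_is_quiescent_peclet(self):
        per = 1e-4
        vs = 0.02
        ratio = quiet_peclet(vs, per, 0.6) * vs**2 * per / 2.0
        assert ratio == pytest.approx(1.0, rel=1e-6)

    def test_degenerate_inputs_raise_naming_quiescent_limit(self):
        with pytest.raises(ParameterError, match="quiescent"):
            theory.effective_peclet(
                dataclasses.replace(groups_of(0.1, 1.0), rel_swim_speed=0.0), 0.0
            )

    @given(per=pers, vs=vss, beta=betas)
    def test_depends_only_on_dimensionless_groups(self, per, vs, beta):
        """Different dimensional realizations of the same (Vs, Per) give the
        same Peclet number through the Deff identity."""
        pe = quiet_peclet(vs, per, beta)
        for L in (200.0, 5000.0):
            gdot = 1.7
            dr = gdot / per
            b = BacteriumParams(
                swim_speed=vs * gdot * L, rot_diffusion=dr, bretherton=beta
            )
            deff = theory.effective_diffusivity(b, gdot)
            assert gdot * L**2 / deff == pytest.approx(pe, rel=1e-12)


class TestEffectiveDiffusivity:
    @given(per=pers, vs=vss, beta=betas)
    def test_identity_with_nondimensional_peclet(self, per, vs, beta):
        gdot, L = 0.9, 750.0
        b = BacteriumParams(
            swim_speed=vs * gdot * L, rot_diffusion=gdot / per, bretherton=beta
        )
        lhs = theory.effective_diffusivity(b, gdot)
        rhs = gdot * L**2 / quiet_peclet(vs, per, beta)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_low_shear_limit_is_quiescent_diffusivity(self, ecoli):
        b = dataclasses.replace(ecoli, thermal_diffusivity=0.0)
        d = theory.effective_diffusivity(b, 1e-8)
        assert d == pytest.approx(b.swim_speed**2 / (2 * b.rot_diffusion), rel=1e-10)

    @given(gdot=st.floats(0.01, 100.0))
    def test_sphere_closed_form(self, gdot):
        b = BacteriumParams(swim_speed=20.0, rot_diffusion=1.5, bretherton=0.0)
        expected = 2 * b.rot_diffusion * b.swim_speed**2 / (
            4 * b.rot_diffusion**2 + gdot**2
        )
        assert theory.effective_diffusivity(b, gdot) == pytest.approx(
            expected, rel=1e-12
        )

    def test_thermal_diffusivity_is_additive(self):
        b0 = BacteriumParams(20.0, 1.0, 0.5)
        b1 = BacteriumParams(20.0, 1.0, 0.5, thermal_diffusivity=0.2)
        assert theory.effective_diffusivity(b1, 2.0) == pytest.approx(
            theory.effective_diffusivity(b0, 2.0) + 0.2, rel=1e-12
        )


class TestBoundaryLayerOrientation:
    def test_zero_gradient_gives_no_bias(self):
        nx, ny = theory.boundary_layer_orientation(0.0, groups_of(0.01, 1.0), 0.5, 0.1)
        assert nx == 0.0 and ny == 0.0

    @given(per=pers, vs=vss, beta=betas, eps=st.floats(1e-3, 0.3))
    def test_vertical_coefficient_reproduces_effective_peclet(self, per, vs, beta, eps):
        """|coefficient of the vertical component| * Vs / eps^2, times eps^3,
        equals 1/Pe_eff: the reduction of the transport balance to the
        Leveque equation."""
        g = groups_of(vs, per)
        _, ny = theory.boundary_layer_orientation(1.0, g, beta, eps)
        lhs = abs(ny) * vs / eps**2 * eps**3
        assert lhs == pytest.approx(1.0 / quiet_peclet(vs, per, beta), rel=1e-12)

    def test_wallward_swimming_for_depletion_gradient(self):
        # density increasing away from the wall: positive vertical gradient
        nx, ny = theory.boundary_layer_orientation(1.0, groups_of(0.01, 1.0), 0.88, 0.1)
        assert ny < 0.0  # net swimming toward the wall
        assert nx < 0.0  # upstream bias


class TestDensityField:
    def test_absorbing_wall_and_far_field(self):
        x = np.array([0.5, 1.0, 3.0])
        assert np.allclose(theory.density_field(x, 0.0, 100.0), 0.0)
        # argument >= 30 at y large
        assert theory.density_field(1.0, 2.0, 100.0) == pytest.approx(1.0, abs=1e-10)

    def test_monotone_in_wall_distance(self):
        y = np.linspace(0.0, 1.0, 200)
        rho = theory.density_field(1.5, y, 50.0)
        assert np.all(np.diff(rho) >= 0.0)
        assert np.all((rho >= 0.0) & (rho <= 1.0))

    def test_invalid_position_raises(self):
        with pytest.raises(ParameterError):
            theory.density_field(0.0, 1.0, 10.0)

    @pytest.mark.parametrize("pe_eff", [1.0, 200.0])
    def test_satisfies_leveque_pde_at_second_order(self, pe_eff):
        """Central-difference residual of y rho_x - (1/Pe) rho_yy converges
        to zero at O(h^2)."""

        def residual(h):
            x0 = 1.3
            y0 = 0.7 * (x0 / pe_eff) ** (1.0 / 3.0)  # inside the layer
            rho_x = (
                theory.density_field(x0 + h, y0, pe_eff)
                - theory.density_field(x0 - h, y0, pe_eff)
            ) / (2 * h)
            rho_yy = (
                theory.density_field(x0, y0 + h, pe_eff)
                - 2 * theory.density_field(x0, y0, pe_eff)
                + theory.density_field(x0, y0 - h, pe_eff)
            ) / h**2
            return abs(y0 * rho_x - rho_yy / pe_eff)

        r1, r2 = residual(1e-2), residual(5e-3)
        order = math.log2(r1 / r2)
        assert order > 1.9


class TestAdhesionRate:
    def test_leveque_prefactor(self):
        assert round(theory.LEVEQUE_PREFACTOR, 3) == 0.538

    def test_reference_point(self):
        assert theory.adhesion_rate(1.0, 1.0) == pytest.approx(0.53837, abs=5e-6)

    @given(x=st.floats(0.01, 10.0), pe=st.floats(1.0, 1e6))
    def test_one_third_power_decay(self, x, pe):
        assert theory.adhesion_rate(8 * x, pe) == pytest.approx(
            0.5 * theory.adhesion_rate(x, pe), rel=1e-12
        )

    @pytest.mark.parametrize("pe_eff,x", [(1.0, 1.0), (300.0, 2.2)])
    def test_equals_wall_flux_of_density_field(self, pe_eff, x):
        delta = 1e-7 * (x / pe_eff) ** (1.0 / 3.0)
        flux = theory.density_field(x, delta, pe_eff) / delta / pe_eff
        assert flux == pytest.approx(theory.adhesion_rate(x, pe_eff), rel=1e-6)

    def test_invalid_position_raises(self):
        with pytest.raises(ParameterError):
            theory.adhesion_rate(-1.0, 10.0)


class TestDimensionalAdhesionRate:
    def test_linear_in_inlet_density(self, ecoli):
        j1 = theory.dimensional_adhesion_rate(100.0, ecoli, 1.0, inlet_density=1.0)
        j2 = theory.dimensional_adhesion_rate(100.0, ecoli, 1.0, inlet_density=2.0)
        assert j2 == pytest.approx(2 * j1, rel=1e-12)

    def test_elongated_bacteria_adhere_less_than_spheres(self):
        sphere = BacteriumParams(22.0, 1.0, 0.0)
        rod = BacteriumParams(22.0, 1.0, 0.88)
        for gdot in (0.2, 1.0, 10.0):
            assert theory.dimensional_adhesion_rate(
                100.0, sphere, gdot
            ) > theory.dimensional_adhesion_rate(100.0, rod, gdot)

    def test_asymptotic_loglog_slopes(self, ecoli):
        """Adhesion grows as shear^(1/3) at low shear and decays as
        shear^(-1) at high shear (motility-only diffusivity: a thermal
        floor would restore passive +1/3 growth at extreme shear)."""
        b = dataclasses.replace(ecoli, thermal_diffusivity=0.0)

        def slope(gdot):
            h = 1.001
            up = theory.dimensional_adhesion_rate(1.0, b, gdot * h)
            dn = theory.dimensional_adhesion_rate(1.0, b, gdot / h)
            return math.log(up / dn) / (2 * math.log(h))

        assert slope(1e-6) == pytest.approx(1.0 / 3.0, abs=1e-3)
        assert slope(1e6) == pytest.approx(-1.0, abs=1e-3)


class TestCriticalShear:
    def test_printed_species_values_at_two_significant_figures(
        self, ecoli, p_aeruginosa
    ):
        assert round(theory.critical_shear(ecoli), 1) == 1.1
        assert round(theory.critical_shear(p_aeruginosa), 3) == 0.039

    def test_sphere_closed_form_and_brute_force(self):
        """For spheres the stationary point of Deff^2 * shear is 2 Dr / sqrt(3);
        cross-checked against a brute-force grid maximization."""
        b = BacteriumParams(swim_speed=18.0, rot_diffusion=0.7, bretherton=0.0)
        got = theory.critical_shear(b)
        assert got == pytest.approx(2 * b.rot_diffusion / math.sqrt(3.0), rel=1e-6)
        grid = np.geomspace(1e-3 * b.rot_diffusion, 1e3 * b.rot_diffusion, 400_001)
        vals = np.array([theory.effective_diffusivity(b, g) for g in grid]) ** 2 * grid
        assert got == pytest.approx(grid[np.argmax(vals)], rel=1e-4)

    def test_scales_linearly_with_rotational_diffusion(self):
        b1 = BacteriumParams(20.0, 1.0, 0.88)
        b2 = BacteriumParams(35.0, 0.05, 0.88)  # swim speed is irrelevant
        assert theory.critical_shear(b2) / theory.critical_shear(b1) == pytest.approx(
            0.05, rel=1e-6
        )

    def test_adhesion_is_unimodal_in_shear(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            b = BacteriumParams(
                swim_speed=rng.uniform(5, 50),
                rot_diffusion=rng.uniform(0.02, 5.0),
                bretherton=rng.uniform(0.0, 0.95),
            )
            grid = np.geomspace(1e-3 * b.rot_diffusion, 1e3 * b.rot_diffusion, 2000)
            vals = np.array(
                [theory.dimensional_adhesion_rate(1.0, b, g) for g in grid]
            )
            sign_changes = np.sum(np.diff(np.sign(np.diff(vals))) != 0)
            assert sign_changes == 1
            i = np.argmax(vals)
            assert 0 < i < len(grid) - 1


class TestNetAdhesion:
    def test_surface_length_scaling(self):
        assert theory.net_adhesion(8.0, 100.0) == pytest.approx(
            4.0 * theory.net_adhesion(1.0, 100.0), rel=1e-12
        )

    def test_matches_adaptive_quadrature(self):
        closed = theory.net_adhesion(3.0, 200.0)
        quad, _ = integrate.quad(lambda x: theory.adhesion_rate(x, 200.0), 0.0, 3.0)
        assert closed == pytest.approx(quad, rel=1e-10)

    def test_vanishes_without_diffusion(self):
        pes = np.geomspace(1.0, 1e12, 13)
        vals = [theory.net_adhesion(3.0, p) for p in pes]
        assert np.all(np.diff(vals) < 0.0)
        assert vals[-1] < 1e-7


class TestScalingCollapse:
    def test_collapse_removes_shape_and_speed_dependence(self):
        """J-bar from the theory is identical for different (beta, Vs) at
        equal Per and surface length."""
        per, ell = 1.7, 3.0
        jbars = []
        for beta, vs in [(0.0, 0.01), (0.88, 0.05), (0.4, 0.002)]:
            pe = quiet_peclet(vs, per, beta)
            net = theory.net_adhesion(ell, pe)
            jbars.append(
                theory.scaled_net_adhesion(net, beta, groups_of(vs, per))
            )
        assert jbars[0] == pytest.approx(jbars[1], rel=1e-10)
        assert jbars[0] == pytest.approx(jbars[2], rel=1e-10)
        assert jbars[0] == pytest.approx(
            theory.collapsed_net_adhesion(ell, per), rel=1e-10
        )

    def test_maximized_at_rotational_peclet_four(self):
        pers_grid = np.geomspace(0.01, 1000.0, 2001)
        vals = [theory.collapsed_net_adhesion(3.0, p) for p in pers_grid]
        assert pers_grid[np.argmax(vals)] == pytest.approx(4.0, rel=5e-3)

    def test_vanishes_in_both_peclet_limits(self):
        assert theory.collapsed_net_adhesion(3.0, 1e-9) < 1e-5
        assert theory.collapsed_net_adhesion(3.0, 1e9) < 1e-5

    def test_quiescent_theory_crossover(self):
        """The quiescent approximation matches the active theory at low Per
        and overestimates grossly at high Per."""
        vs = 0.01
        for per, lo, hi in [(1e-3, 0.999, 1.001), (1e3, 0.0, 1e-3)]:
            g = groups_of(vs, per)
            active = theory.adhesion_rate(1.0, quiet_peclet(vs, per, 0.5))
            quies = theory.adhesion_rate(1.0, theory.quiescent_peclet(g))
            assert lo <= active / quies <= hi


class TestRegimeClassification:
    def test_fast_swimmers_are_region_A(self):
        lab = theory.classify_regime(groups_of(1.5, 1.0), 0.0)
        assert lab.label == "A"

    def test_ecoli_in_small_catheter_is_valid(self, ecoli):
        from active_leveque.parameters import get_scenario

        flow = get_scenario("small_catheter").flow()  # mid-range shear
        g = dimensionless_groups(ecoli, flow)
        assert theory.classify_regime(g, ecoli.bretherton).label == "VALID"

    def test_failure_regions_each_reachable(self):
        # B: boundary layer thinner than a cell body (computed epsilon)
        assert theory.classify_regime(groups_of(5e-5, 50.0), 0.0).label == "B"
        # C: reorientation dominant
        assert theory.classify_regime(groups_of(0.01, 3000.0), 0.0).label == "C"
        # D: swimming weak enough for active stresses to matter
        assert theory.classify_regime(groups_of(2e-4, 1.0), 0.0).label == "D"

    def test_precedence_A_first(self):
        lab = theory.classify_regime(groups_of(1.5, 5000.0), 0.0)
        assert lab.label == "A"

    def test_thresholds_recorded(self):
        lab = theory.classify_regime(groups_of(0.02, 1.0), 0.0)
        assert lab.label == "VALID"
        assert lab.eps_threshold == 5e-4
        assert lab.epsilon == pytest.approx(
            quiet_peclet(0.02, 1.0, 0.0) ** (-1.0 / 3.0), rel=1e-12
        )


class TestTheoryCurve:
    def test_local_rate_decreasing_and_net_consistent(self):
        curve = theory.theory_curve(groups_of(0.02, 1.0), 0.0, surface_length=3.0)
        assert np.all(np.diff(curve.local_rate) < 0.0)
        quad = np.trapezoid(curve.local_rate, curve.positions)
        # trapezoid misses the integrable x^{-1/3} singularity near 0;
        # compare on the resolved part of the surface
        x0 = curve.positions[0]
        pe = curve.meta["eff_peclet"]
        analytic_tail = theory.net_adhesion(3.0, pe) - theory.net_adhesion(x0, pe)
        assert quad == pytest.approx(analytic_tail, rel=1e-3)

    def test_csv_export_has_header(self, tmp_path):
        curve = theory.theory_curve(groups_of(0.02, 1.0), 0.0)
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        text = path.read_text()
        assert text.startswith("#")
        assert "Per = 1.0" in text


class TestHalfDensityContour:
    def test_matches_root_finding_oracle(self):
        pe = 4000.0
        for x in (0.5, 1.5, 3.0):
            y_closed = theory.halfdensity_contour(x, pe)
            y_root = optimize.brentq(
                lambda y: theory.density_field(x, y, pe) - 0.5, 1e-9, 1.0
            )
            assert y_closed == pytest.approx(y_root, rel=1e-10)
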