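"""Capping thermodynamics: energy terms, solver, surface arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanocolloid import capping
from nanocolloid.capping import (CoreSpec, LigandSpec, capping_energy,
                                 capping_profile, citrate_preset,
                                 coverage_fraction, interpolate_alpha,
                                 ligand_repulsion_mean_field,
                                 polar_solvation_born,
                                 projected_area_distribution, solve_capping,
                                 surface_properties)
from nanocolloid.constants import KE_KCAL_NM_E2


def fibonacci_sphere(n, radius):
    i = np.arange(n)
    phi = np.pi * (3 - np.sqrt(5)) * i
    z = 1 - (2 * i + 1) / n
    r = np.sqrt(1 - z * z)
    return radius * np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def pairwise_coulomb(points, q):
    e = 0.0
    for i in range(len(points)):
        d = np.linalg.norm(points[i + 1:] - points[i], axis=1)
        e += KE_KCAL_NM_E2 * q * q * np.sum(1.0 / d)
    return e


class TestCappingEnergy:
    def test_empty_cap_is_zero(self, citrate2):
        ligand, core = citrate2
        assert capping_energy(0, ligand, core) == 0.0

    def test_null_parameters_give_zero(self):
        ligand = LigandSpec(alpha=2, desolv_energy=0.0, binding_energy=0.0)
        core = CoreSpec()
        # alpha fixes the charge, so cancel the electrostatics explicitly
        zero = lambda n, l, c: 0.0
        for n in (0, 1, 7, 50):
            assert capping_energy(n, ligand, core, repulsion_term=zero,
                                  polar_term=zero) == 0.0

    def test_negative_n_rejected(self, citrate2):
        ligand, core = citrate2
        with pytest.raises(ValueError):
            capping_energy(-1, ligand, core)

    def test_mean_field_repulsion_bounds_spread_layout(self):
        """The mean-field shell repulsion is the uniform-random-placement
        expectation: an upper bound on a spread-out (Fibonacci) layout,
        with a relative gap that shrinks as n grows."""
        ligand = LigandSpec(alpha=2, desolv_energy=0.0, binding_energy=0.0)
        core = CoreSpec(reference_radius=1.30)
        gaps = []
        for n in (10, 40, 160):
            mean_field = ligand_repulsion_mean_field(n, ligand, core)
            explicit = pairwise_coulomb(fibonacci_sphere(n, 1.30), -2)
            assert mean_field >= explicit
            gaps.append((mean_field - explicit) / mean_field)
        assert gaps[0] == pytest.approx(0.269, abs=0.02)  # frozen oracle value
        assert gaps[0] > gaps[1] > gaps[2]

    def test_quadratic_coefficient_identity(self, citrate2):
        """dG_cap is exactly quadratic in N; the quadratic coefficient is
        k_e q^2 (1/(2 R_c) - (1 - 1/eps_w)/(2 R_s))."""
        ligand, core = citrate2
        prof = capping_profile(ligand, core, 60)
        coeffs = np.polyfit(prof.n_values, prof.total, 2)
        q = ligand.charge_per_ligand
        expected = KE_KCAL_NM_E2 * q * q * (
            1.0 / (2 * core.reference_radius)
            - (1 - 1 / core.solvent_rel_permittivity)
            / (2 * core.solvation_radius))
        assert coeffs[0] == pytest.approx(expected, rel=1e-9)

    def test_repulsion_scales_as_n_squared(self, citrate3):
        ligand, core = citrate3
        ratios = [ligand_repulsion_mean_field(n, ligand, core) / n**2
                  for n in (10, 100, 1000, 10000)]
        assert np.ptp(ratios[-2:]) / ratios[-1] < 1e-3

    def test_polar_term_nonpositive_quadratic(self, citrate2):
        ligand, core = citrate2
        vals = np.array([polar_solvation_born(n, ligand, core)
                         for n in range(0, 50)])
        assert np.all(vals <= 0)
        resid = vals - np.polyval(np.polyfit(np.arange(50), vals, 2),
                                  np.arange(50))
        assert np.max(np.abs(resid)) < 1e-8

    def test_linear_terms_shift_linearly(self, citrate2):
        ligand, core = citrate2
        shifted = LigandSpec(alpha=ligand.alpha,
                             desolv_energy=2 * ligand.desolv_energy,
                             binding_energy=2 * ligand.binding_energy)
        delta = (ligand.desolv_energy + ligand.binding_energy)
        for n in (1, 13, 60):
            assert capping_energy(n, shifted, core) - \
                capping_energy(n, ligand, core) == pytest.approx(n * delta)


class TestSolver:
    def test_citrate_minima(self, citrate2, citrate3):
        assert solve_capping(*citrate2).n_opt == 28
        assert solve_capping(*citrate3).n_opt == 33

    def test_single_deprotonation_has_no_minimum(self):
        sol = solve_capping(*citrate_preset(1))
        assert not sol.has_stable_minimum
        assert sol.n_opt is None

    def test_repulsive_ligand_does_not_bind(self):
        ligand = LigandSpec(alpha=1, desolv_energy=5.0, binding_energy=10.0)
        assert not solve_capping(ligand, CoreSpec()).has_stable_minimum

    def test_agrees_with_independent_rescan(self, citrate2):
        ligand, core = citrate2
        sol = solve_capping(ligand, core, 120)
        brute = min(range(121), key=lambda n: capping_energy(n, ligand, core))
        assert sol.n_opt == brute

    def test_stronger_charge_weakly_decreases_n_opt(self):
        """With a positive quadratic coefficient (repulsion-dominated
        geometry), more ligand charge means fewer bound ligands."""
        core = CoreSpec(vdw_radius=1.5, reference_radius=1.3,
                        solvation_radius=1.5)
        n_opts = []
        for alpha in (1, 2, 3):
            ligand = LigandSpec(alpha=alpha, desolv_energy=10.0,
                                binding_energy=-500.0)
            sol = solve_capping(ligand, core, 400)
            n_opts.append(sol.n_opt)
        assert n_opts[0] >= n_opts[1] >= n_opts[2]

    def test_n_max_validation(self, citrate2):
        with pytest.raises(ValueError):
            solve_capping(*citrate2, n_max=0)


class TestSurfaceArithmetic:
    def test_net_charges_match_stoichiometry(self, citrate2, citrate3):
        _, _, net2 = surface_properties(28, *citrate2)
        _, _, net3 = surface_properties(33, *citrate3)
        assert net2 == -56.0
        assert net3 == -99.0

    def test_zero_ligands(self, citrate2):
        assert surface_properties(0, *citrate2) == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize("net,expected_sigma",
                             [(-40, 1.9), (-13, 0.6), (-87, 4.1),
                              (-56, 2.6), (-99, 4.7)])
    def test_sigma_convention(self, net, expected_sigma):
        area = 4 * np.pi * 1.30**2
        assert round(abs(net) / area, 1) == expected_sigma


class TestCoverage:
    def test_zero(self, citrate2):
        ligand, _ = citrate2
        assert coverage_fraction(0, ligand, 20.0) == 0.0

    def test_ratio_is_stoichiometric(self, citrate2, citrate3):
        lig2, _ = citrate2
        lig3, _ = citrate3
        for area in (15.0, 19.9, 21.2):
            ratio = coverage_fraction(33, lig3, area) / \
                coverage_fraction(28, lig2, area)
            assert ratio == pytest.approx(33 / 28)

    def test_printed_percentage_implies_reference_area(self, citrate2):
        # 28 x 0.16 nm^2 at 22.5% coverage -> ~19.9 nm^2 reference area
        lig, _ = citrate2
        area = 28 * lig.projected_area / 0.225
        assert area == pytest.approx(19.9, abs=0.05)
        assert coverage_fraction(28, lig, area) == pytest.approx(0.225)

    def test_clamped_with_warning(self, citrate2):
        lig, _ = citrate2
        with pytest.warns(UserWarning):
            assert coverage_fraction(1000, lig, 1.0) == 1.0

    def test_bad_area(self, citrate2):
        with pytest.raises(ValueError):
            coverage_fraction(1, citrate2[0], 0.0)


class TestAlphaInterpolation:
    def test_dft_affinity_maps_to_intermediate_state(self):
        alpha = interpolate_alpha([(2, 20.0), (3, 53.1)], 40.9)
        assert alpha == pytest.approx(2.631, abs=0.005)

    def test_endpoint(self):
        assert interpolate_alpha([(2, 20.0), (3, 53.1)], 20.0) == 2.0

    def test_collinear_points_match_two_point_fit(self):
        two = interpolate_alpha([(1, 10.0), (3, 30.0)], 17.5)
        three = interpolate_alpha([(1, 10.0), (2, 20.0), (3, 30.0)], 17.5)
        assert two == pytest.approx(three)

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            interpolate_alpha([(1, 10.0), (2, 5.0), (3, 30.0)], 8.0)

    def test_extrapolation_warns(self):
        with pytest.warns(UserWarning):
            interpolate_alpha([(2, 20.0), (3, 53.1)], 60.0)

    @given(st.floats(10.1, 29.9))
    @settings(max_examples=25, deadline=None)
    def test_linear_identity(self, target):
        # for points on an exact line, interpolation inverts the line
        alpha = interpolate_alpha([(1, 10.0), (3, 30.0)], target)
        assert alpha == pytest.approx((target - 10.0) / 10.0 + 1.0)


class TestProjectedArea:
    def test_single_sphere_rotation_invariant(self):
        areas, mode = projected_area_distribution(
            [(np.zeros((1, 3)), np.array([0.2]))], n_orientations=4,
            grid_step=0.01, seed=0)
        assert np.allclose(areas, np.pi * 0.04, atol=0.01 * 2 * np.pi * 0.2)
        assert np.ptp(areas) < 1e-12

    def test_disjoint_spheres_axial_vs_perpendicular(self):
        from nanocolloid.capping import _rasterized_projected_area
        pos = np.array([[0.0, 0, 0], [0, 0, 1.0]])
        rad = np.array([0.2, 0.2])
        axial = _rasterized_projected_area(pos, rad, 0.005)
        perp = _rasterized_projected_area(pos[:, [0, 2, 1]], rad, 0.005)
        assert axial == pytest.approx(np.pi * 0.04, rel=0.02)
        assert perp == pytest.approx(2 * np.pi * 0.04, rel=0.02)

    def test_cluster_matches_monte_carlo(self, rng):
        from nanocolloid.capping import _rasterized_projected_area
        pos = rng.uniform(-0.3, 0.3, (5, 3))
        rad = rng.uniform(0.1, 0.25, 5)
        raster = _rasterized_projected_area(pos, rad, 0.005)
        lo = (pos[:, :2] - rad[:, None]).min(0)
        hi = (pos[:, :2] + rad[:, None]).max(0)
        pts = rng.uniform(lo, hi, (200000, 2))
        inside = np.zeros(len(pts), bool)
        for (cx, cy, _), r in zip(pos, rad):
            inside |= (pts[:, 0] - cx)**2 + (pts[:, 1] - cy)**2 <= r * r
        mc = inside.mean() * np.prod(hi - lo)
        assert raster == pytest.approx(mc, rel=0.02)

    def test_bad_grid_step(self):
        with pytest.raises(ValueError):
            projected_area_distribution([(np.zeros((1, 3)), np.ones(1))],
                                        grid_step=0.0)


class TestSpecValidation:
    def test_ligand_charge_is_minus_alpha(self):
        for alpha in (1, 2, 3):
            lig = LigandSpec(alpha=alpha, desolv_energy=1.0,
                             binding_energy=-1.0)
            assert lig.charge_per_ligand == -alpha

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            LigandSpec(alpha=4, desolv_energy=1.0, binding_energy=-1.0)

    def test_core_radius_ordering(self):
        with pytest.raises(ValueError):
            CoreSpec(vdw_radius=1.0, reference_radius=1.5)

    def test_born_sphere_inside_vdw_warns(self):
        with pytest.warns(UserWarning):
            CoreSpec(vdw_radius=1.5, reference_radius=1.3,
                     solvation_radius=1.3)
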