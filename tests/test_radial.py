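"""1-D radial solver: oracles, conservation laws, grid robustness."""

import math

import numpy as np
import pytest
import scipy.special as spc

from pbcharge.core import (
    IonizableGroup,
    IonizableGroupSet,
    SolutionConditions,
    dh_sphere_surface_potential,
    ionization_fraction,
)
from pbcharge.exceptions import GeometryError
from pbcharge.models import CylinderModel, SphereModel
from pbcharge.radial import (
    electrolyte_ion_charge,
    free_energy,
    gauss_charge,
    net_charge,
    solve_cylinder_infinite,
    solve_slab,
    solve_sphere,
)


class TestSphereSolver:
    def test_zero_charge_gives_zero_field(self, cond_100mM, acid_pka4):
        model = SphereModel(radius=3.0, interior_dielectric=78.5,
                            frozen_charge=0.0)
        fld = solve_sphere(model, cond_100mM)
        assert np.max(np.abs(fld.psi)) < 1e-12

    def test_debye_hueckel_limit(self, cond_100mM, acid_pka4):
        # single charge, no dielectric contrast: linearized surface potential
        model = SphereModel(radius=2.0, interior_dielectric=78.5,
                            groups=IonizableGroupSet.single(acid_pka4, 1))
        fld = solve_sphere(model, cond_100mM)
        expected = dh_sphere_surface_potential(-1.0, 2.0, cond_100mM)
        assert fld.surface_potential == pytest.approx(expected, rel=0.02)

    def test_regulation_benchmark(self, cond_100mM, regulation78_sphere):
        # compact sphere: ~78% of the structural charge survives regulation
        fld = solve_sphere(regulation78_sphere, cond_100mM)
        eta = net_charge(fld) / -12.75
        assert eta == pytest.approx(0.78, abs=0.03)

    def test_gauss_law_matches_density_integral(self, cond_100mM,
                                                regulation78_sphere):
        fld = solve_sphere(regulation78_sphere, cond_100mM, mesh_scale=0.5)
        qs = net_charge(fld)
        assert gauss_charge(fld, 5.1 + 1e-9) == pytest.approx(qs, rel=0.01)

    def test_electroneutrality(self, cond_100mM, regulation78_sphere):
        fld = solve_sphere(regulation78_sphere, cond_100mM)
        assert electrolyte_ion_charge(fld) == pytest.approx(-net_charge(fld),
                                                            rel=0.01)

    def test_grid_convergence(self, cond_100mM, regulation78_sphere):
        # halving every mesh length scale moves q_s and F by < 1%
        f1 = solve_sphere(regulation78_sphere, cond_100mM, mesh_scale=1.0)
        f2 = solve_sphere(regulation78_sphere, cond_100mM, mesh_scale=0.5)
        assert net_charge(f2) == pytest.approx(net_charge(f1), rel=0.01)
        assert free_energy(f2) == pytest.approx(free_energy(f1), rel=0.01)

    def test_domain_size_independence(self, cond_100mM, regulation78_sphere):
        q10 = net_charge(solve_sphere(regulation78_sphere, cond_100mM, n_debye=10))
        q15 = net_charge(solve_sphere(regulation78_sphere, cond_100mM, n_debye=15))
        assert q15 == pytest.approx(q10, rel=0.005)

    def test_newton_picard_agreement(self, cond_100mM, regulation78_sphere):
        fld = solve_sphere(regulation78_sphere, cond_100mM)
        psi_p, ok, _ = fld.payload["problem"].solve_picard(relax=0.6)
        assert ok
        assert np.max(np.abs(psi_p - fld.psi)) < 1e-4

    def test_free_energy_scales_quadratically_weak_charge(self):
        # kappa R << 1, constant charge: linear-regime self energy ~ Q^2
        cond = SolutionConditions(ph=7.0, salt_molarity=0.001)
        f1 = free_energy(solve_sphere(
            SphereModel(radius=1.0, interior_dielectric=78.5, frozen_charge=-1.0),
            cond))
        f2 = free_energy(solve_sphere(
            SphereModel(radius=1.0, interior_dielectric=78.5, frozen_charge=-2.0),
            cond))
        assert f2 == pytest.approx(4.0 * f1, rel=0.05)


class TestCylinderSolver:
    def test_zero_sigma_zero_field(self, cond_100mM):
        phosphate = IonizableGroup(pka=2.0, valence=-1)
        model = CylinderModel(radius=1.0, length=math.inf,
                              surface_groups=IonizableGroupSet.single(phosphate, 1e-12),
                              regulation_enabled=False)
        fld = solve_cylinder_infinite(model, cond_100mM)
        assert np.max(np.abs(fld.psi)) < 1e-10

    def test_linearized_bessel_oracle(self, cond_100mM):
        # low charge, kappa R = 1: psi_s = 4 pi lB sigma K0(kR)/(k K1(kR))
        R = cond_100mM.debye_length
        lam = 0.02
        g = IonizableGroup(pka=2.0, valence=-1)
        model = CylinderModel(radius=R, length=math.inf,
                              surface_groups=IonizableGroupSet.single(g, lam),
                              regulation_enabled=False)
        fld = solve_cylinder_infinite(model, cond_100mM)
        k = cond_100mM.kappa
        sigma = -lam * ionization_fraction(g, 7.0) / (2 * math.pi * R)
        exact = (4 * math.pi * cond_100mM.bjerrum_length * sigma
                 * spc.k0(k * R) / (k * spc.k1(k * R)))
        assert fld.surface_potential == pytest.approx(exact, rel=0.05)

    def test_nonlinear_screening_reduces_magnitude(self, cond_100mM,
                                                   dsdna_infinite):
        # dsDNA-like line density: |psi_s| falls below the linearized estimate
        fld = solve_cylinder_infinite(dsdna_infinite, cond_100mM)
        k = cond_100mM.kappa
        sigma = net_charge(fld) / (2 * math.pi * 1.0)
        linear = (4 * math.pi * cond_100mM.bjerrum_length * sigma
                  * spc.k0(k) / (k * spc.k1(k)))
        assert abs(fld.surface_potential) < abs(linear)

    def test_dsdna_regulation_is_small(self, dsdna_infinite):
        # strong acids at pH 7: regulated and structural charge within 5%
        for c in (0.001, 0.1):
            cond = SolutionConditions(ph=7.0, salt_molarity=c)
            fld = solve_cylinder_infinite(dsdna_infinite, cond)
            q_str = -2.0 / 0.34 * ionization_fraction(
                dsdna_infinite.surface_groups.groups[0][0], 7.0)
            assert abs(net_charge(fld) - q_str) / abs(q_str) < 0.05

    def test_infinite_frozen_charge_rejected(self):
        model = CylinderModel(radius=1.0, length=math.inf, frozen_charge=-5.0,
                              regulation_enabled=False)
        cond = SolutionConditions(ph=7.0, salt_molarity=0.1)
        with pytest.raises(GeometryError):
            solve_cylinder_infinite(model, cond)


class TestSlab:
    def test_two_wall_superposition(self, cond_fast2d):
        # kappa h = 4: interior follows psi_w (e^-kz + e^-k(2h-z)) closely
        from pbcharge.renormalization import wall_sigma_for_potential

        k = cond_fast2d.kappa
        h = 4.0 / k
        sigma = wall_sigma_for_potential(cond_fast2d, -0.5)
        fld = solve_slab(h, sigma, cond_fast2d)
        z = np.linspace(0.5 / k, 2 * h - 0.5 / k, 31)
        psi_w = fld.psi_at(0.0)
        superpos = psi_w * (np.exp(-k * z) + np.exp(-k * (2 * h - z)))
        dev = np.max(np.abs(fld.psi_at(z) - superpos)) / np.max(np.abs(superpos))
        assert dev < 0.03

    def test_wall_potential_tracks_gouy_chapman_target(self, cond_fast2d):
        from pbcharge.renormalization import wall_sigma_for_potential

        k = cond_fast2d.kappa
        sigma = wall_sigma_for_potential(cond_fast2d, -0.5)
        fld = solve_slab(4.0 / k, sigma, cond_fast2d)
        assert fld.psi_at(0.0) == pytest.approx(-0.5, abs=0.02)
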