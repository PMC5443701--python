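"""Regulated charge, titration, pI, eps_p inference, core-shell pKa shifts."""

from dataclasses import replace

import numpy as np
import pytest

from pbcharge.core import IonizableGroup, IonizableGroupSet
from pbcharge.exceptions import NotFoundError
from pbcharge.models import CoreShellModel, SphereModel
from pbcharge import regulation as reg


GLU = IonizableGroup(pka=4.3, valence=-1, label="GLU")


class TestRegulatedCharge:
    def test_benchmark_eta(self, cond_100mM, regulation78_sphere):
        rep = reg.regulated_charge(regulation78_sphere, cond_100mM)
        assert rep.eta_g == pytest.approx(0.78, abs=0.03)
        assert abs(rep.q_s) <= abs(rep.q_str) + 1e-9

    def test_weak_charge_high_dielectric_no_regulation(self, cond_100mM,
                                                       acid_pka4):
        model = SphereModel(radius=3.0, interior_dielectric=78.5,
                            groups=IonizableGroupSet.single(acid_pka4, 0.05))
        rep = reg.regulated_charge(model, cond_100mM)
        assert rep.eta_g == pytest.approx(1.0, abs=0.01)

    def test_lower_salt_strengthens_regulation(self, cond_100mM,
                                               regulation78_sphere):
        low = replace(cond_100mM, salt_molarity=0.001)
        eta_hi = reg.regulated_charge(regulation78_sphere, cond_100mM).eta_g
        eta_lo = reg.regulated_charge(regulation78_sphere, low).eta_g
        assert eta_lo < eta_hi

    def test_eta_monotone_in_interior_dielectric(self, cond_100mM,
                                                 regulation78_sphere):
        etas = [
            reg.regulated_charge(
                replace(regulation78_sphere, interior_dielectric=eps), cond_100mM
            ).eta_g
            for eps in (4.0, 10.0, 20.0, 40.0, 78.5)
        ]
        assert all(a < b for a, b in zip(etas, etas[1:]))

    def test_frozen_model_reports_identity(self, cond_100mM):
        model = SphereModel(radius=3.0, interior_dielectric=20.0,
                            frozen_charge=-7.5)
        rep = reg.regulated_charge(model, cond_100mM)
        assert rep.q_s == rep.q_str == -7.5 and rep.eta_g == 1.0


@pytest.fixture(scope="module")
def symmetric_model():
    acid = IonizableGroup(pka=4.0, valence=-1, label="acid")
    base = IonizableGroup(pka=10.0, valence=1, label="base")
    return SphereModel(radius=2.0, interior_dielectric=78.5,
                       groups=IonizableGroupSet(((acid, 5), (base, 5))))


class TestTitration:
    def test_acid_only_curve_non_increasing(self, cond_100mM, acid_pka4):
        model = SphereModel(radius=2.0, interior_dielectric=40.0,
                            groups=IonizableGroupSet.single(acid_pka4, 5))
        curve = reg.titration_curve(model, cond_100mM, np.arange(2.0, 12.1, 1.0))
        assert np.all(np.diff(curve.q_s) <= 1e-9)

    def test_symmetric_pair_isoelectric_point(self, cond_100mM, symmetric_model):
        curve = reg.titration_curve(symmetric_model, cond_100mM,
                                    np.arange(3.0, 11.01, 0.5))
        signs = np.sign(curve.q_s[np.abs(curve.q_s) > 1e-9])
        assert len(np.nonzero(np.diff(signs))[0]) == 1  # single crossing
        assert reg.isoelectric_point(curve) == pytest.approx(7.0, abs=0.05)

    def test_extra_base_raises_pi(self, cond_100mM, symmetric_model):
        base = IonizableGroup(pka=10.0, valence=1, label="base")
        shifted = replace(
            symmetric_model,
            groups=symmetric_model.groups.with_extra(((base, 1),)),
        )
        grid = np.arange(3.0, 11.01, 0.5)
        pi0 = reg.isoelectric_point(
            reg.titration_curve(symmetric_model, cond_100mM, grid))
        pi1 = reg.isoelectric_point(
            reg.titration_curve(shifted, cond_100mM, grid))
        assert pi1 > pi0

    def test_no_crossing_raises(self, cond_100mM, acid_pka4):
        model = SphereModel(radius=2.0, interior_dielectric=78.5,
                            groups=IonizableGroupSet.single(acid_pka4, 5))
        curve = reg.titration_curve(model, cond_100mM, np.arange(6.0, 9.1, 1.0))
        with pytest.raises(NotFoundError):
            reg.isoelectric_point(curve)

    def test_cylinder_surface_curve_tracks_surface_potential(self, cond_100mM,
                                                             dsdna_infinite):
        # self-consistency: q_s equals the ideal fraction evaluated at psi_s
        from pbcharge.core import ionization_fraction
        from pbcharge.radial import net_charge, solve_cylinder_infinite

        fld = solve_cylinder_infinite(dsdna_infinite, cond_100mM)
        g, lam = dsdna_infinite.surface_groups.groups[0]
        expected = lam * g.valence * ionization_fraction(
            g, cond_100mM.ph, fld.surface_potential)
        assert net_charge(fld) == pytest.approx(expected, rel=1e-6)


class TestDielectricInference:
    def test_round_trip(self, cond_100mM, regulation78_sphere):
        q20 = reg.regulated_charge(regulation78_sphere, cond_100mM).q_s
        eps = reg.infer_interior_dielectric(regulation78_sphere, cond_100mM, q20)
        assert eps == pytest.approx(20.0, rel=0.01)

    def test_unattainable_charge_raises(self, cond_100mM, regulation78_sphere):
        with pytest.raises(NotFoundError):
            reg.infer_interior_dielectric(regulation78_sphere, cond_100mM, -20.0)


class TestCoreShellPka:
    def test_bulk_like_environment_near_nominal(self, cond_100mM):
        # everything at the water dielectric, no shell charge: only the small
        # smeared-charge self-interaction offsets the nominal pKa upward
        model = CoreShellModel(outer_radius=2.2, core_radius=0.6,
                               core_dielectric=78.5, shell_dielectric=78.5,
                               core_group=GLU, shell_charge=0.0)
        pka = reg.core_shell_pka(model, cond_100mM)
        assert 4.3 <= pka < 4.7

    def test_buried_core_range_with_positive_shell(self, cond_100mM):
        # eps_s = 40, eps_c in [10, 25], positively charged shell: the
        # predicted pKa spans several units, highest for the least polar core
        pkas = {}
        for eps_c in (10.0, 25.0):
            model = CoreShellModel(outer_radius=2.2, core_radius=0.6,
                                   core_dielectric=eps_c, shell_dielectric=40.0,
                                   core_group=GLU, shell_charge=8.0)
            pkas[eps_c] = reg.core_shell_pka(model, cond_100mM)
        assert pkas[10.0] > pkas[25.0]
        assert pkas[10.0] - pkas[25.0] > 2.0
        assert 4.3 < pkas[25.0] < 5.5 and 7.0 < pkas[10.0] < 9.5

    def test_smaller_core_shifts_pka_up(self, cond_100mM):
        base = CoreShellModel(outer_radius=2.2, core_radius=0.6,
                              core_dielectric=10.0, shell_dielectric=40.0,
                              core_group=GLU, shell_charge=8.0)
        small = replace(base, core_radius=0.5)
        shift = reg.core_shell_pka(small, cond_100mM) - reg.core_shell_pka(
            base, cond_100mM)
        assert 0.02 < shift < 0.3

    def test_born_attenuation_reduces_shift(self, cond_100mM):
        lys = IonizableGroup(pka=10.4, valence=1, label="LYS")
        full = CoreShellModel(outer_radius=2.2, core_radius=0.6,
                              core_dielectric=10.0, shell_dielectric=40.0,
                              core_group=lys, shell_charge=8.0)
        damped = replace(full, born_attenuation=0.25)
        pka_full = reg.core_shell_pka(full, cond_100mM)
        pka_damped = reg.core_shell_pka(damped, cond_100mM)
        # basic group: burial pushes pKa down; damping p<1 moderates the shift
        assert pka_full < pka_damped < 10.4
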