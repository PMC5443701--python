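"""Closed-form physics: lengths, ionization, Born term, thresholds, Manning."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from pbcharge.core import (
    IonizableGroup,
    IonizableGroupSet,
    SolutionConditions,
    bjerrum_length,
    born_term,
    debye_length,
    dh_sphere_surface_potential,
    dsdna_manning_parameter,
    ionization_fraction,
    manning_fraction,
    mean_interior_potential,
    structural_charge,
    threshold_charge,
    threshold_potential,
)
from pbcharge.exceptions import InvalidParameterError


class TestScreeningLengths:
    @pytest.mark.parametrize(
        "eps, expected",
        [(78.5, 0.7139609), (40.0, 1.4011483)],
    )
    def test_bjerrum_reference_values(self, eps, expected):
        assert bjerrum_length(eps, 298.15) == pytest.approx(expected, rel=1e-6)

    def test_bjerrum_inverse_proportionality(self):
        assert bjerrum_length(78.5) / bjerrum_length(39.25) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "molarity, expected",
        [(0.1, 0.9619830), (0.001, 9.6198300)],
    )
    def test_debye_reference_values(self, molarity, expected):
        cond = SolutionConditions(ph=7.0, salt_molarity=molarity)
        assert debye_length(cond) == pytest.approx(expected, rel=1e-6)

    def test_debye_square_root_scaling(self):
        c1 = SolutionConditions(ph=7.0, salt_molarity=0.05)
        c2 = SolutionConditions(ph=7.0, salt_molarity=0.05 / 100)
        assert debye_length(c2) / debye_length(c1) == pytest.approx(10.0)

    def test_invalid_parameters_raise(self):
        with pytest.raises(InvalidParameterError):
            bjerrum_length(-1.0)
        with pytest.raises(InvalidParameterError):
            SolutionConditions(ph=7.0, salt_molarity=-0.1)


class TestIonization:
    def test_half_ionization_at_pka(self):
        g = IonizableGroup(pka=4.0, valence=-1)
        assert ionization_fraction(g, ph=4.0) == pytest.approx(0.5)

    def test_hand_evaluated_potential_shift(self):
        # acid at pH = pKa with psi~ = -ln 3: mass-action factor becomes 3
        g = IonizableGroup(pka=4.0, valence=-1)
        a = ionization_fraction(g, ph=4.0, psi_local=-math.log(3.0))
        assert a == pytest.approx(0.25, rel=1e-12)

    def test_large_born_penalty_discharges(self):
        g = IonizableGroup(pka=4.0, valence=-1)
        assert ionization_fraction(g, ph=7.0, phi_s=80.0) < 1e-30

    @settings(max_examples=60, derandomize=True)
    @given(
        z=st.sampled_from([-1, 1]),
        ph=st.floats(2.0, 12.0),
        psi=st.floats(-5.0, 5.0),
        phi1=st.floats(0.0, 10.0),
        dphi=st.floats(0.01, 5.0),
    )
    def test_monotone_decreasing_in_phi_s(self, z, ph, psi, phi1, dphi):
        g = IonizableGroup(pka=6.0, valence=z)
        a1 = ionization_fraction(g, ph, psi, phi1)
        a2 = ionization_fraction(g, ph, psi, phi1 + dphi)
        assert a2 < a1

    @settings(max_examples=60, derandomize=True)
    @given(ph=st.floats(2.0, 12.0), psi=st.floats(-5.0, 5.0),
           dpsi=st.floats(0.01, 3.0))
    def test_acid_ionization_increasing_in_psi(self, ph, psi, dpsi):
        # a positive local potential repels protons and ionizes acids; the
        # negative potential a charged acidic molecule generates therefore
        # discharges its own groups (the regulation feedback)
        g = IonizableGroup(pka=6.0, valence=-1)
        assert ionization_fraction(g, ph, psi + dpsi) > ionization_fraction(g, ph, psi)


class TestBornTerm:
    def test_carboxyl_reference_value(self, cond_100mM):
        assert born_term(40.0, cond_100mM, 0.25, 1.0) == pytest.approx(1.374, abs=0.001)

    def test_no_contrast_gives_zero(self, cond_100mM):
        assert born_term(78.5, cond_100mM, 0.25) == 0.0

    def test_low_dielectric_value(self, cond_100mM):
        assert born_term(10.0, cond_100mM, 0.25) == pytest.approx(9.781, abs=0.001)

    def test_never_negative(self, cond_100mM):
        # interior more polarizable than water is clamped, per the >= 0 constraint
        assert born_term(120.0, cond_100mM, 0.25) == 0.0

    def test_attenuation_scales_linearly(self, cond_100mM):
        full = born_term(40.0, cond_100mM, 0.25, 1.0)
        assert born_term(40.0, cond_100mM, 0.25, 0.25) == pytest.approx(0.25 * full)


class TestStructuralCharge:
    def test_half_ionization_single_group(self, acid_pka4):
        gs = IonizableGroupSet.single(acid_pka4, 1)
        assert structural_charge(gs, ph=4.0) == pytest.approx(-0.5)

    def test_symmetric_acid_base_cancellation(self):
        # pKa offsets of equal magnitude on either side of the pH cancel exactly
        acid = IonizableGroup(pka=4.0, valence=-1)
        base = IonizableGroup(pka=10.4, valence=1)
        gs = IonizableGroupSet(((acid, 10), (base, 10)))
        assert structural_charge(gs, ph=7.2) == pytest.approx(0.0, abs=1e-12)

    def test_full_ionization_limit(self, acid_pka4):
        gs = IonizableGroupSet.single(acid_pka4, 25)
        assert structural_charge(gs, ph=13.0) == pytest.approx(-25.0, rel=1e-6)


class TestThreshold:
    def test_reference_potential(self):
        assert threshold_potential(7.0, 4.0, 0.95) == pytest.approx(3.963316, rel=1e-6)

    def test_vanishes_at_pka_half(self):
        assert threshold_potential(4.0, 4.0, 0.5) == 0.0

    def test_born_penalty_lowers_threshold(self):
        assert threshold_potential(7.0, 4.0, 0.95, 1.4) == pytest.approx(
            2.563316, rel=1e-6
        )

    def test_rule_of_thumb_criterion(self, cond_100mM):
        psi_t = threshold_potential(7.0, 4.0, 0.95)
        res = threshold_charge(2.55, 20.0, cond_100mM, psi_t,
                               surface_potential_contribution=2.0)
        assert round(res.dimensionless_criterion, -1) == 10  # one significant figure

    def test_criterion_below_five_with_born(self, cond_100mM):
        psi_t = threshold_potential(7.0, 4.0, 0.95, 1.4)
        res = threshold_charge(2.55, 20.0, cond_100mM, psi_t,
                               surface_potential_contribution=2.0)
        assert res.dimensionless_criterion < 5.0

    def test_equality_back_substitution(self, cond_100mM):
        # |Qt| inserted into the mean-interior-potential expression returns psi_t
        psi_t = threshold_potential(7.0, 4.0, 0.95)
        for R in (1.0, 2.55, 5.1):
            res = threshold_charge(R, 20.0, cond_100mM, psi_t)
            back = abs(
                mean_interior_potential(res.Q_t, R, 20.0)
                + dh_sphere_surface_potential(res.Q_t, R, cond_100mM)
            )
            assert back == pytest.approx(psi_t, rel=1e-12)

    def test_degenerate_when_born_dominates(self, cond_100mM):
        res = threshold_charge(2.55, 20.0, cond_100mM, 0.0)
        assert res.degenerate and res.Q_t == 0.0


class TestSpherePotentials:
    def test_dh_surface_reference(self, cond_100mM):
        val = dh_sphere_surface_potential(12.75, 5.1, cond_100mM)
        assert val == pytest.approx(0.2832482, rel=1e-6)

    def test_dh_linearity_and_zero(self, cond_100mM):
        assert dh_sphere_surface_potential(0.0, 5.1, cond_100mM) == 0.0
        assert dh_sphere_surface_potential(2.0, 5.1, cond_100mM) == pytest.approx(
            2.0 * dh_sphere_surface_potential(1.0, 5.1, cond_100mM)
        )

    def test_mean_interior_vs_radial_quadrature(self):
        # volume average of the parabolic interior profile, numerically
        Q, R, eps_p = 7.0, 3.0, 20.0
        lb_p = bjerrum_length(eps_p)

        def psi(r):
            return Q * lb_p * (R * R - r * r) / (2.0 * R**3)

        num, _ = integrate.quad(lambda r: psi(r) * 4 * math.pi * r * r, 0, R)
        num /= 4.0 / 3.0 * math.pi * R**3
        assert mean_interior_potential(Q, R, eps_p) == pytest.approx(num, rel=1e-9)

    def test_mean_interior_dielectric_scaling(self):
        assert mean_interior_potential(5.0, 2.0, 10.0) == pytest.approx(
            2.0 * mean_interior_potential(5.0, 2.0, 20.0)
        )


class TestManning:
    def test_dsdna_fraction(self):
        assert manning_fraction(4.2) == pytest.approx(1 / 4.2)

    @pytest.mark.parametrize("xi", [0.5, 1.0])
    def test_no_condensation_below_threshold(self, xi):
        assert manning_fraction(xi) == 1.0

    def test_dsdna_parameter(self, cond_100mM):
        assert dsdna_manning_parameter(cond_100mM) == pytest.approx(4.1998, abs=1e-3)

    def test_parameter_scalings(self, cond_100mM):
        base = dsdna_manning_parameter(cond_100mM, 0.34)
        assert dsdna_manning_parameter(cond_100mM, 0.68) == pytest.approx(base / 2)
        c40 = SolutionConditions(ph=7.0, salt_molarity=0.1, solvent_dielectric=40.0)
        assert dsdna_manning_parameter(c40) == pytest.approx(base * 78.5 / 40.0)


class TestGroupSetValidation:
    def test_rejects_all_zero_counts(self, acid_pka4):
        with pytest.raises(InvalidParameterError):
            IonizableGroupSet(((acid_pka4, 0),))

    def test_rejects_bad_valence(self):
        with pytest.raises(InvalidParameterError):
            IonizableGroup(pka=4.0, valence=2)

    def test_full_ionization_charge(self, acid_pka4):
        base = IonizableGroup(pka=10.0, valence=1)
        gs = IonizableGroupSet(((acid_pka4, 3), (base, 5)))
        assert gs.full_ionization_charge == pytest.approx(2.0)
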