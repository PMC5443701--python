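"""Closed-form electrostatics and ionization chemistry.

Everything in this module is computable without solving a PDE: Bjerrum and
Debye lengths, Henderson-Hasselbalch / regulated ionization fractions, the
Born solvation penalty for burying an ionized group in a low-dielectric
interior, structural (ideal) charge, the analytical charge-regulation
threshold criterion for a uniformly charged dielectric sphere, and the
classical Manning counterion-condensation fraction used as a comparator for
cylindrical polyelectrolytes.

Units: lengths nm, potentials dimensionless (e*psi/kBT), energies kBT,
charges in elementary charges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    AVOGADRO,
    BOLTZMANN,
    DEFAULT_ION_RADIUS,
    DEFAULT_TEMPERATURE,
    ELEMENTARY_CHARGE,
    NM,
    VACUUM_PERMITTIVITY,
    WATER_DIELECTRIC,
)
from .exceptions import InvalidParameterError

__all__ = [
    "SolutionConditions",
    "IonizableGroup",
    "IonizableGroupSet",
    "ThresholdResult",
    "bjerrum_length",
    "debye_length",
    "ionization_fraction",
    "born_term",
    "structural_charge",
    "threshold_potential",
    "threshold_charge",
    "dh_sphere_surface_potential",
    "mean_interior_potential",
    "manning_fraction",
    "dsdna_manning_parameter",
]

LN10 = math.log(10.0)


def bjerrum_length(dielectric: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Bjerrum length e^2 / (4 pi eps eps0 kBT) in nm.

    Separation at which two elementary charges in a medium of relative
    dielectric constant ``dielectric`` interact with energy kBT.
    """
    if dielectric <= 0:
        raise InvalidParameterError(f"dielectric must be positive, got {dielectric}")
    if temperature <= 0:
        raise InvalidParameterError(f"temperature must be positive, got {temperature}")
    lb_m = ELEMENTARY_CHARGE**2 / (
        4.0 * math.pi * dielectric * VACUUM_PERMITTIVITY * BOLTZMANN * temperature
    )
    return lb_m / NM


@dataclass(frozen=True)
class SolutionConditions:
    """Bulk solution state: pH, monovalent salt, temperature, solvent dielectric.

    The salt is symmetric 1:1; protons enter the ionization chemistry but are
    neglected in the screening (valid for pH 5-9 where [H+] << c).
    """

    ph: float
    salt_molarity: float  # mol/L
    temperature: float = DEFAULT_TEMPERATURE  # K
    solvent_dielectric: float = WATER_DIELECTRIC

    def __post_init__(self):
        if not (0.0 <= self.ph <= 14.0):
            raise InvalidParameterError(f"pH must lie in [0, 14], got {self.ph}")
        if self.salt_molarity <= 0:
            raise InvalidParameterError(
                f"salt molarity must be positive, got {self.salt_molarity}"
            )
        if self.temperature <= 0:
            raise InvalidParameterError("temperature must be positive")
        if self.solvent_dielectric <= 1:
            raise InvalidParameterError("solvent dielectric must exceed 1")

    @property
    def bjerrum_length(self) -> float:
        """lB in the solvent, nm."""
        return bjerrum_length(self.solvent_dielectric, self.temperature)

    @property
    def debye_length(self) -> float:
        """kappa^-1 in nm."""
        return debye_length(self)

    @property
    def kappa(self) -> float:
        """Inverse Debye length, 1/nm."""
        return 1.0 / self.debye_length

    @property
    def salt_number_density(self) -> float:
        """Bulk salt number density per species, 1/nm^3."""
        return self.salt_molarity * AVOGADRO * 1e3 * NM**3


def debye_length(cond: SolutionConditions) -> float:
    """Debye screening length kappa^-1 = sqrt(eps eps0 kBT / (2 NA c e^2)) in nm."""
    if cond.salt_molarity <= 0:
        raise InvalidParameterError("salt molarity must be positive")
    c_per_m3 = cond.salt_molarity * AVOGADRO * 1e3
    k2 = (
        2.0
        * c_per_m3
        * ELEMENTARY_CHARGE**2
        / (
            cond.solvent_dielectric
            * VACUUM_PERMITTIVITY
            * BOLTZMANN
            * cond.temperature
        )
    )
    return 1.0 / (math.sqrt(k2) * NM)


@dataclass(frozen=True)
class IonizableGroup:
    """One titratable species: pKa, formal valence of the charged state, size."""

    pka: float
    valence: int  # +1 basic, -1 acidic
    ion_radius: float = DEFAULT_ION_RADIUS  # nm, for the Born term
    label: str = ""

    def __post_init__(self):
        if self.valence not in (-1, 1):
            raise InvalidParameterError(f"valence must be +1 or -1, got {self.valence}")
        if not (0.0 < self.pka < 14.0):
            raise InvalidParameterError(f"pKa must lie in (0, 14), got {self.pka}")
        if self.ion_radius <= 0:
            raise InvalidParameterError("ion radius must be positive")


@dataclass(frozen=True)
class IonizableGroupSet:
    """Inventory of titratable species: list of (group, count)."""

    groups: tuple = field(default_factory=tuple)  # tuple[(IonizableGroup, count)]

    def __post_init__(self):
        groups = tuple((g, float(n)) for g, n in self.groups)
        object.__setattr__(self, "groups", groups)
        if any(n < 0 for _, n in groups):
            raise InvalidParameterError("group counts must be non-negative")
        if not any(n > 0 for _, n in groups):
            raise InvalidParameterError("need at least one group with positive count")

    @classmethod
    def single(cls, group: IonizableGroup, count: float) -> "IonizableGroupSet":
        return cls(((group, count),))

    @property
    def total_count(self) -> float:
        return sum(n for _, n in self.groups)

    @property
    def full_ionization_charge(self) -> float:
        """Signed charge if every group were fully ionized."""
        return sum(g.valence * n for g, n in self.groups)

    def with_extra(self, extra) -> "IonizableGroupSet":
        return IonizableGroupSet(self.groups + tuple(extra))


def ionization_fraction(
    group: IonizableGroup,
    ph: float,
    psi_local: float = 0.0,
    phi_s: float = 0.0,
    phi_0: float = 0.0,
):
    """Fractional ionization of a titratable group in a local environment.

    alpha = 1 / (1 + 10^{z(pH - pKa)} exp(z psi~ + phi_s + phi_0)).

    With psi~ = phi_s = phi_0 = 0 this is the ideal Henderson-Hasselbalch
    fraction; a positive local potential discharges bases and ionizes acids,
    and the solvation penalty phi_s >= 0 discharges both.  Accepts array
    ``psi_local``; saturates smoothly at 0 and 1.
    """
    if phi_s < 0:
        raise InvalidParameterError("phi_s must be non-negative")
    z = group.valence
    # exponent of the mass-action factor; clip to avoid overflow in exp
    expo = z * (ph - group.pka) * LN10 + z * np.asarray(psi_local, float) + phi_s + phi_0
    expo = np.clip(expo, -700.0, 700.0)
    out = 1.0 / (1.0 + np.exp(expo))
    return float(out) if np.isscalar(psi_local) or np.ndim(psi_local) == 0 else out


def ionization_fraction_derivative(
    group: IonizableGroup, ph: float, psi_local, phi_s: float = 0.0, phi_0: float = 0.0
):
    """d alpha / d psi~ = -z alpha (1 - alpha); used in Newton Jacobians."""
    a = ionization_fraction(group, ph, psi_local, phi_s, phi_0)
    return -group.valence * a * (1.0 - a)


def born_term(
    interior_dielectric: float,
    cond: SolutionConditions,
    ion_radius: float = DEFAULT_ION_RADIUS,
    attenuation: float = 1.0,
) -> float:
    """Born solvation penalty (kBT) for an ionized group buried in the interior.

    phi_s = p * (lB,m / 2 rA) * (eps_m/eps_p - 1), clamped at zero (no reward
    for an interior more polarizable than the solvent).  ``attenuation`` is the
    multiplicative damping parameter p in (0, 1].
    """
    if ion_radius <= 0:
        raise InvalidParameterError("ion radius must be positive")
    if interior_dielectric <= 0:
        raise InvalidParameterError("interior dielectric must be positive")
    if not (0.0 < attenuation <= 1.0):
        raise InvalidParameterError("attenuation p must lie in (0, 1]")
    lb_m = bjerrum_length(cond.solvent_dielectric, cond.temperature)
    val = attenuation * lb_m / (2.0 * ion_radius) * (
        cond.solvent_dielectric / interior_dielectric - 1.0
    )
    return max(val, 0.0)


def structural_charge(groups: IonizableGroupSet, ph: float) -> float:
    """Ideal (structural) charge q_str in e: sum of z * alpha at zero potential."""
    return sum(
        n * g.valence * ionization_fraction(g, ph) for g, n in groups.groups
    )


def threshold_potential(
    ph: float, pka: float, eta_t: float, phi_s: float = 0.0
) -> float:
    """Magnitude of the local potential at which regulation sets in (kBT/e).

    |psi_t| = |ln10 (pH - pKa) + ln(1/eta_t - 1)| - phi_s, floored at zero.
    ``eta_t`` is the ionization fraction defining the regulation onset
    (e.g. 0.95: the group has lost 5% of its ideal charge).
    """
    if not (0.0 < eta_t < 1.0):
        raise InvalidParameterError("eta_t must lie strictly in (0, 1)")
    chem = abs(LN10 * (ph - pka) + math.log(1.0 / eta_t - 1.0))
    return max(chem - phi_s, 0.0)


@dataclass(frozen=True)
class ThresholdResult:
    """Threshold charge for the onset of regulation in a uniform sphere."""

    psi_t: float  # threshold potential magnitude, kBT/e
    Q_t: float  # threshold number of charges (magnitude)
    dimensionless_criterion: float  # |Qt| lB,p / R
    degenerate: bool = False  # True when phi_s wiped out the chemistry term


def threshold_charge(
    radius: float,
    interior_dielectric: float,
    cond: SolutionConditions,
    psi_t: float,
    surface_potential_contribution: float | None = None,
) -> ThresholdResult:
    """Solve the interior-potential threshold condition at equality for |Qt|.

    The mean interior potential of a uniformly charged dielectric sphere,
    |Q| (lB,p/5R + lB,w/(R(1+kappa R))), is equated to ``psi_t``.  When
    ``surface_potential_contribution`` is given (the |psi_s| ~ 2 kBT estimate
    valid at high salt) the surface term is replaced by that fixed offset:
    |Qt| lB,p/(5R) = psi_t - |psi_s|, which yields the rule-of-thumb
    |Qt| lB,p/R ~ 10 at pH - pKa = 3.
    """
    if radius <= 0:
        raise InvalidParameterError("radius must be positive")
    lb_p = bjerrum_length(interior_dielectric, cond.temperature)
    lb_w = cond.bjerrum_length
    if psi_t <= 0:
        return ThresholdResult(psi_t=0.0, Q_t=0.0, dimensionless_criterion=0.0, degenerate=True)
    if surface_potential_contribution is None:
        kr = cond.kappa * radius
        denom = lb_p / (5.0 * radius) + lb_w / (radius * (1.0 + kr))
        q_t = psi_t / denom
        return ThresholdResult(psi_t, q_t, q_t * lb_p / radius)
    eff = psi_t - abs(surface_potential_contribution)
    if eff <= 0:
        return ThresholdResult(psi_t=psi_t, Q_t=0.0, dimensionless_criterion=0.0, degenerate=True)
    q_t = 5.0 * radius * eff / lb_p
    return ThresholdResult(psi_t, q_t, q_t * lb_p / radius)


def dh_sphere_surface_potential(
    charge: float, radius: float, cond: SolutionConditions
) -> float:
    """Debye-Hueckel surface potential of a sphere: Q lB,w / (R (1 + kappa R))."""
    if radius <= 0:
        raise InvalidParameterError("radius must be positive")
    return charge * cond.bjerrum_length / (radius * (1.0 + cond.kappa * radius))


def mean_interior_potential(
    charge: float,
    radius: float,
    interior_dielectric: float,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Volume-averaged interior potential of a uniformly charged sphere.

    For psi(r) = (rho/3 eps_p eps0)(R^2 - r^2)/2 the volume average is
    Q lB,p / (5 R), with lB,p the Bjerrum length at the interior dielectric.
    """
    if radius <= 0:
        raise InvalidParameterError("radius must be positive")
    lb_p = bjerrum_length(interior_dielectric, temperature)
    return charge * lb_p / (5.0 * radius)


def manning_fraction(manning_parameter: float) -> float:
    """Classical condensation fraction: min(1, 1/xi) with xi = lB / charge spacing."""
    if manning_parameter <= 0:
        raise InvalidParameterError("Manning parameter must be positive")
    return min(1.0, 1.0 / manning_parameter)


def dsdna_manning_parameter(
    cond: SolutionConditions, rise_per_bp: float = 0.34
) -> float:
    """Manning parameter of dsDNA: lB,w * (2 charges per base-pair rise)."""
    if rise_per_bp <= 0:
        raise InvalidParameterError("rise per base pair must be positive")
    return cond.bjerrum_length * 2.0 / rise_per_bp
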