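"""Molecule geometry models and the slit geometry for interaction runs.

A model couples a coarse geometry (sphere, hollow cylinder, core-shell
sphere) to an inventory of ionizable groups and the dielectric description of
the interior.  Models are immutable; solver entry points live in
:mod:`pbcharge.radial`, :mod:`pbcharge.fem`, :mod:`pbcharge.regulation` and
:mod:`pbcharge.renormalization`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .core import IonizableGroup, IonizableGroupSet, SolutionConditions, born_term
from .exceptions import GeometryError, InvalidParameterError

__all__ = ["SphereModel", "CylinderModel", "CoreShellModel", "SlitGeometry"]


@dataclass(frozen=True)
class SphereModel:
    """Globular molecule: dielectric sphere with a uniform volume density of groups.

    ``frozen_charge`` switches the sphere to constant-charge mode (total charge
    in e, regulation off) for renormalization runs.
    """

    radius: float  # nm
    interior_dielectric: float
    groups: IonizableGroupSet | None = None
    born_attenuation: float = 1.0
    phi_0: float = 0.0
    frozen_charge: float | None = None

    def __post_init__(self):
        if self.radius <= 0:
            raise GeometryError("sphere radius must be positive")
        if self.interior_dielectric < 1:
            raise InvalidParameterError("interior dielectric must be >= 1")
        if self.groups is None and self.frozen_charge is None:
            raise InvalidParameterError("need ionizable groups or a frozen charge")

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius**3

    @property
    def surface_area(self) -> float:
        return 4.0 * math.pi * self.radius**2

    def volume_densities(self):
        """[(group, number density / nm^3), ...] for the uniform distribution."""
        if self.groups is None:
            return []
        return [(g, n / self.volume) for g, n in self.groups.groups]

    def phi_s(self, cond: SolutionConditions, group: IonizableGroup) -> float:
        """Born penalty for this group inside the sphere (kBT)."""
        return born_term(
            self.interior_dielectric, cond, group.ion_radius, self.born_attenuation
        )

    def frozen(self, charge: float) -> "SphereModel":
        """Constant-charge copy carrying ``charge`` (e) on its surface."""
        return replace(self, frozen_charge=float(charge))


@dataclass(frozen=True)
class CylinderModel:
    """Linear polyelectrolyte: rigid hollow cylinder with surface groups.

    The ionizable groups sit on the cylinder surface, fully exposed to the
    electrolyte, so no interior dielectric (or Born term) enters.  ``length``
    may be ``math.inf`` for the 1-D radial treatment.  ``frozen_charge``
    (total, e) switches to constant-charge mode.
    """

    radius: float  # nm (= D/2)
    length: float  # nm or math.inf
    surface_groups: IonizableGroupSet | None = None
    regulation_enabled: bool = True
    frozen_charge: float | None = None

    def __post_init__(self):
        if self.radius <= 0:
            raise GeometryError("cylinder radius must be positive")
        if not (self.length > 0):
            raise GeometryError("cylinder length must be positive (or inf)")
        if self.surface_groups is None and self.frozen_charge is None:
            raise InvalidParameterError("need surface groups or a frozen charge")

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.length)

    @property
    def surface_area(self) -> float:
        """Side plus end caps (closed hollow cylinder), nm^2."""
        if self.is_infinite:
            return math.inf
        return 2.0 * math.pi * self.radius * self.length + 2.0 * math.pi * self.radius**2

    def surface_densities(self):
        """[(group, surface number density / nm^2), ...]."""
        if self.surface_groups is None:
            return []
        area = self.surface_area
        if math.isinf(area):
            raise GeometryError(
                "surface densities of an infinite cylinder are per-length; "
                "use line_densities()"
            )
        return [(g, n / area) for g, n in self.surface_groups.groups]

    def line_densities(self):
        """[(group, count per nm of contour), ...].

        For infinite cylinders the group counts are interpreted as densities
        per nm of contour length; finite cylinders divide by the length.
        """
        if self.surface_groups is None:
            return []
        if self.is_infinite:
            return list(self.surface_groups.groups)
        return [(g, n / self.length) for g, n in self.surface_groups.groups]

    def frozen(self, charge: float) -> "CylinderModel":
        return replace(self, frozen_charge=float(charge), regulation_enabled=False)


@dataclass(frozen=True)
class CoreShellModel:
    """Sphere with a small low-dielectric core housing one titratable residue.

    Used for pKa-shift prediction: the shell carries the molecule's background
    formal charge (uniform volume density, pH-independent when given as a
    total), the core carries the single group of interest whose Born penalty
    is evaluated with the core dielectric and the attenuation p.
    """

    outer_radius: float  # nm
    core_radius: float  # nm
    core_dielectric: float
    shell_dielectric: float
    core_group: IonizableGroup
    shell_charge: float = 0.0  # total background charge in e, uniform in shell
    born_attenuation: float = 1.0
    phi_0: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.core_radius < self.outer_radius):
            raise GeometryError("need 0 < core radius < outer radius")
        if self.core_dielectric < 1 or self.shell_dielectric < 1:
            raise InvalidParameterError("dielectric constants must be >= 1")

    @property
    def core_volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.core_radius**3

    @property
    def shell_volume(self) -> float:
        return 4.0 / 3.0 * math.pi * (self.outer_radius**3 - self.core_radius**3)

    def core_phi_s(self, cond: SolutionConditions) -> float:
        return born_term(
            self.core_dielectric, cond, self.core_group.ion_radius, self.born_attenuation
        )


@dataclass(frozen=True)
class SlitGeometry:
    """Parallel-plate slit of height 2h with like-charged walls.

    The object sits at the mid-plane z = h; the inter-surface separation is
    z* = h - R (sphere) or h - L/2 (cylinder).  ``wall_surface_charge`` is in
    e/nm^2 (signed); ``lateral_extent`` is the radial truncation r_max.
    """

    half_height: float  # h, nm
    wall_surface_charge: float  # e/nm^2
    lateral_extent: float  # nm

    def __post_init__(self):
        if self.half_height <= 0 or self.lateral_extent <= 0:
            raise GeometryError("slit dimensions must be positive")

    def object_gap(self, half_extent: float) -> float:
        """z* = h - (object half-extent along the symmetry axis)."""
        gap = self.half_height - half_extent
        if gap <= 0:
            raise GeometryError("object does not fit in the slit")
        return gap
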