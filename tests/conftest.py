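import math

import pytest

from pbcharge.core import (
    IonizableGroup,
    IonizableGroupSet,
    SolutionConditions,
)
from pbcharge.models import CylinderModel, SphereModel


@pytest.fixture(scope="session")
def cond_100mM():
    """pH 7, 100 mM monovalent salt, water at 25 C."""
    return SolutionConditions(ph=7.0, salt_molarity=0.1)


@pytest.fixture(scope="session")
def cond_fast2d():
    """Conditions with kappa^-1 ~ 2 nm: small 2-D domains for cheap FEM tests."""
    return SolutionConditions(ph=7.0, salt_molarity=0.0231)


@pytest.fixture(scope="session")
def acid_pka4():
    return IonizableGroup(pka=4.0, valence=-1, label="acid")


@pytest.fixture(scope="session")
def regulation78_sphere(acid_pka4):
    """The compact-sphere benchmark: Q/R = 2.5 /nm, eps_p = 20, Born term on."""
    return SphereModel(
        radius=5.1,
        interior_dielectric=20.0,
        groups=IonizableGroupSet.single(acid_pka4, 12.75),
    )


@pytest.fixture(scope="session")
def dsdna_infinite(acid_pka4):
    """Infinite dsDNA-like cylinder: 2 phosphate charges per 0.34 nm, pKa 2."""
    phosphate = IonizableGroup(pka=2.0, valence=-1, label="phosphate")
    return CylinderModel(
        radius=1.0,
        length=math.inf,
        surface_groups=IonizableGroupSet.single(phosphate, 2.0 / 0.34),
        regulation_enabled=True,
    )
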