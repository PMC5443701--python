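"""Physical constants (CODATA 2018) and shipped chemistry defaults.

All package-internal lengths are in nanometres, energies in units of kBT,
electrical potentials dimensionless (psi~ = e*psi/kBT) and charges in units of
the elementary charge e.  Conversion to SI happens only at the boundaries of
the package.
"""

from __future__ import annotations

import importlib.resources

import yaml

# CODATA 2018 exact / recommended values (SI)
ELEMENTARY_CHARGE = 1.602176634e-19  # C
BOLTZMANN = 1.380649e-23  # J/K
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
AVOGADRO = 6.02214076e23  # 1/mol

#: metres per nanometre
NM = 1e-9

#: default solvent: water at 25 C
DEFAULT_TEMPERATURE = 298.15  # K
WATER_DIELECTRIC = 78.5

#: default radius of an ionized group (used for the Born solvation term), nm
DEFAULT_ION_RADIUS = 0.25

#: contour rise per monomer for fully extended chains, nm
RISE_PER_RESIDUE = 0.38  # polypeptide
RISE_PER_BASE = 0.34  # nucleic acid (per base or base pair)

#: hollow-cylinder diameters representing linear molecules, nm
CYLINDER_DIAMETERS = {"protein": 0.5, "ssDNA": 1.0, "dsDNA": 2.0}


def load_pka_table() -> dict:
    """Return the shipped default pKa/valence table as a dict.

    The table lives in ``pbcharge/data/pka_defaults.yaml`` and every entry can
    be overridden by the caller (see :func:`pbcharge.sequences.build_from_sequence`).
    """
    ref = importlib.resources.files("pbcharge.data").joinpath("pka_defaults.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)
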