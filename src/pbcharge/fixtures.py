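"""Canonical benchmark fixtures: every test input is generated, none shipped.

Each :class:`FixtureCase` couples a molecule/condition pair to its expected
value and a provenance tag:

* ``"published"``  - value printed in the source experimental/theory table
* ``"derived"``    - value computed from an independent closed form or oracle
* ``"trivial"``    - value forced by symmetry or a limiting case

``generate_fixtures`` serializes the set as deterministic JSON for CLI use.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

from .core import (
    IonizableGroup,
    IonizableGroupSet,
    SolutionConditions,
)
from .models import CoreShellModel, CylinderModel, SphereModel

__all__ = ["FixtureCase", "canonical_fixtures", "generate_fixtures", "build_model"]


@dataclass(frozen=True)
class FixtureCase:
    name: str
    description: str
    task: str  # qstr | qs | qeff | threshold | born | sweep | slab
    model: dict  # serialized model spec (see build_model)
    conditions: dict
    expected: dict  # quantity -> value
    provenance: str  # published | derived | trivial
    rel_tolerance: float


def _cond(ph, c):
    return {"ph": ph, "salt_molarity": c}


def build_model(spec: dict):
    """Instantiate a molecule model from a fixture/config dict."""
    kind = spec["kind"]
    if kind == "sphere":
        groups = None
        if "groups" in spec:
            groups = IonizableGroupSet(tuple(
                (IonizableGroup(pka=g["pka"], valence=g["valence"],
                                ion_radius=g.get("ion_radius", 0.25),
                                label=g.get("label", "")), g["count"])
                for g in spec["groups"]
            ))
        return SphereModel(
            radius=spec["radius"],
            interior_dielectric=spec.get("interior_dielectric", 78.5),
            groups=groups,
            born_attenuation=spec.get("born_attenuation", 1.0),
            frozen_charge=spec.get("frozen_charge"),
        )
    if kind == "cylinder":
        groups = None
        if "groups" in spec:
            groups = IonizableGroupSet(tuple(
                (IonizableGroup(pka=g["pka"], valence=g["valence"],
                                label=g.get("label", "")), g["count"])
                for g in spec["groups"]
            ))
        length = spec["length"]
        return CylinderModel(
            radius=spec["radius"],
            length=math.inf if length == "inf" else length,
            surface_groups=groups,
            regulation_enabled=spec.get("regulation_enabled", True),
            frozen_charge=spec.get("frozen_charge"),
        )
    if kind == "core_shell":
        g = spec["core_group"]
        return CoreShellModel(
            outer_radius=spec["outer_radius"],
            core_radius=spec["core_radius"],
            core_dielectric=spec["core_dielectric"],
            shell_dielectric=spec["shell_dielectric"],
            core_group=IonizableGroup(pka=g["pka"], valence=g["valence"],
                                      label=g.get("label", "")),
            shell_charge=spec.get("shell_charge", 0.0),
            born_attenuation=spec.get("born_attenuation", 1.0),
        )
    raise ValueError(f"unknown model kind {kind!r}")


def conditions_from(spec: dict) -> SolutionConditions:
    return SolutionConditions(**spec)


def canonical_fixtures() -> list[FixtureCase]:
    """The benchmark set exercised by the acceptance machinery."""
    acid4 = {"pka": 4.0, "valence": -1, "label": "acid"}
    return [
        FixtureCase(
            name="born_carboxyl_eps40",
            description="Born solvation penalty of an ionized carboxyl "
                        "(rA=0.25 nm) moved into an eps_p=40 interior",
            task="born",
            model={"kind": "sphere", "radius": 1.0, "interior_dielectric": 40.0,
                   "groups": [dict(acid4, count=1)]},
            conditions=_cond(7.0, 0.1),
            expected={"phi_s_kBT": 1.4},
            provenance="published",
            rel_tolerance=0.04,
        ),
        FixtureCase(
            name="threshold_rule_of_thumb",
            description="Regulation-onset criterion |Qt| lB_p/R with the "
                        "high-salt surface-potential estimate of 2 kBT",
            task="threshold",
            model={"kind": "sphere", "radius": 2.55, "interior_dielectric": 20.0,
                   "groups": [dict(acid4, count=1)]},
            conditions=_cond(7.0, 0.1),
            expected={"criterion": 10.0, "eta_t": 0.95, "pka": 4.0,
                      "psi_s_kBT": 2.0, "phi_s": 0.0},
            provenance="published",
            rel_tolerance=0.05,
        ),
        FixtureCase(
            name="threshold_with_born",
            description="Same criterion with the phi_s=1.4 kBT anion "
                        "solvation penalty: drops below 5",
            task="threshold",
            model={"kind": "sphere", "radius": 2.55, "interior_dielectric": 20.0,
                   "groups": [dict(acid4, count=1)]},
            conditions=_cond(7.0, 0.1),
            expected={"criterion_upper_bound": 5.0, "eta_t": 0.95, "pka": 4.0,
                      "psi_s_kBT": 2.0, "phi_s": 1.4},
            provenance="published",
            rel_tolerance=0.0,
        ),
        FixtureCase(
            name="regulation_78_percent",
            description="Compact sphere Q/R=2.5/nm, eps_p=20, Born term on: "
                        "78% regulation at pH 7, 100 mM",
            task="qs",
            model={"kind": "sphere", "radius": 5.1, "interior_dielectric": 20.0,
                   "groups": [dict(acid4, count=12.75)]},
            conditions=_cond(7.0, 0.1),
            expected={"eta_g": 0.78},
            provenance="published",
            rel_tolerance=0.04,
        ),
        FixtureCase(
            name="dsdna_40bp_effective_charge",
            description="40 bp dsDNA as a constant-charge cylinder, 1 mM",
            task="qeff",
            model={"kind": "cylinder", "radius": 1.0, "length": 40 * 0.34,
                   "frozen_charge": -80.3, "regulation_enabled": False},
            conditions=_cond(8.8, 0.001),
            expected={"q_eff_abs": 32.4},
            provenance="published",
            rel_tolerance=0.10,
        ),
        FixtureCase(
            name="dsdna_60bp_effective_charge",
            description="60 bp dsDNA as a constant-charge cylinder, 1 mM",
            task="qeff",
            model={"kind": "cylinder", "radius": 1.0, "length": 60 * 0.34,
                   "frozen_charge": -121.4, "regulation_enabled": False},
            conditions=_cond(8.8, 0.001),
            expected={"q_eff_abs": 45.7},
            provenance="published",
            rel_tolerance=0.10,
        ),
        FixtureCase(
            name="globular_sphere_effective_charge",
            description="Globular-protein-size sphere (R=5.1 nm, Q=-21.5 e) "
                        "in 1 mM: renormalization negligible",
            task="qeff",
            model={"kind": "sphere", "radius": 5.1, "interior_dielectric": 11.0,
                   "frozen_charge": -21.5},
            conditions=_cond(8.8, 0.001),
            expected={"q_eff_abs": 21.5},
            provenance="published",
            rel_tolerance=0.05,
        ),
        FixtureCase(
            name="manning_comparison_grid",
            description="Infinite constant-charge cylinders, kappa R = 0.1: "
                        "eta_n vs the Manning fraction across lB/lambda",
            task="sweep",
            model={"kind": "cylinder", "radius": 1.0, "length": "inf",
                   "frozen_charge": -1.0, "regulation_enabled": False},
            conditions=_cond(7.0, (0.9607 / 10.0) ** 2 * 0.1),
            expected={"manning_parameters": [2.0, 3.0, 4.2, 5.0, 6.0],
                      "rms_rel_dev_upper_bound_pct": 10.0},
            provenance="published",
            rel_tolerance=0.0,
        ),
        FixtureCase(
            name="debye_hueckel_sphere",
            description="Weakly charged sphere: surface potential matches "
                        "the linearized Q lB/(R(1+kR)) form",
            task="qs",
            model={"kind": "sphere", "radius": 2.0, "interior_dielectric": 78.5,
                   "groups": [dict(acid4, count=1)]},
            conditions=_cond(7.0, 0.1),
            expected={"surface_potential_rel_err_bound": 0.05},
            provenance="derived",
            rel_tolerance=0.0,
        ),
        FixtureCase(
            name="empty_slit_superposition",
            description="Empty charged slit, kappa h = 4: interior potential "
                        "follows the two-wall exponential superposition",
            task="slab",
            model={"kind": "sphere", "radius": 0.5, "interior_dielectric": 78.5,
                   "frozen_charge": 0.0},
            conditions=_cond(7.0, 0.0231),
            expected={"wall_psi": -0.5, "kappa_h": 4.0,
                      "superposition_rel_err_bound": 0.03},
            provenance="published",
            rel_tolerance=0.0,
        ),
    ]


def generate_fixtures(output_dir) -> list[Path]:
    """Write the canonical fixture set as deterministic JSON files."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for case in canonical_fixtures():
        p = out / f"{case.name}.json"
        with open(p, "w") as fh:
            json.dump(asdict(case), fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths.append(p)
    return paths
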