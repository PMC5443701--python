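"""Regulated charge, titration curves, pI, dielectric inference, pKa shifts.

The true (regulated) charge q_s of a molecule follows from the converged PB
field by integrating the self-consistently ionized charge density; the
regulation factor eta_g = q_s / q_str measures how much the local potential
and the Born solvation penalty suppress ionization relative to the ideal
Henderson-Hasselbalch value.  Sweeping pH gives titration curves and the
isoelectric point; root-finding on the interior dielectric constant against a
measured charge yields an effective eps_p; integrating the charge of a single
buried group in a core-shell sphere across pH yields its shifted pKa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as _dcfield, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import SolutionConditions, structural_charge
from .exceptions import InvalidParameterError, NotFoundError, SolverError
from .fem import solve_axisymmetric
from .fem import object_charge as fem_object_charge
from .models import CoreShellModel, CylinderModel, SphereModel
from .radial import (
    core_charge,
    net_charge,
    solve_core_shell,
    solve_cylinder_infinite,
    solve_sphere,
)

__all__ = [
    "ChargeReport",
    "TitrationCurve",
    "regulated_charge",
    "titration_curve",
    "isoelectric_point",
    "infer_interior_dielectric",
    "core_shell_pka",
]


@dataclass
class ChargeReport:
    """Structural vs regulated charge of one molecule at one condition."""

    q_str: float  # e (ideal Henderson-Hasselbalch)
    q_s: float  # e (regulated)
    eta_g: float  # q_s / q_str
    conditions: SolutionConditions
    model_summary: str
    diagnostics: dict = _dcfield(default_factory=dict)

    def summary(self) -> str:
        return "\n".join([
            "Charge regulation report",
            f"  model                 : {self.model_summary}",
            f"  pH / salt             : {self.conditions.ph} / "
            f"{1e3 * self.conditions.salt_molarity:g} mM",
            f"  structural charge qstr: {self.q_str:+.3f} e",
            f"  regulated charge qs   : {self.q_s:+.3f} e",
            f"  regulation factor     : {self.eta_g:.4f}",
        ])

    def to_dict(self) -> dict:
        return {
            "q_str": self.q_str,
            "q_s": self.q_s,
            "eta_g": self.eta_g,
            "ph": self.conditions.ph,
            "salt_molarity": self.conditions.salt_molarity,
            "model": self.model_summary,
        }


@dataclass
class TitrationCurve:
    """q_s(pH) plus per-group mean ionization fractions."""

    ph: np.ndarray
    q_s: np.ndarray
    q_str: np.ndarray
    alpha: dict  # label -> array of mean ionized fraction per pH
    failed: np.ndarray  # bool mask of pH points whose solve failed

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"pH": self.ph, "q_s": self.q_s, "q_str": self.q_str})
        for k, v in self.alpha.items():
            df[f"alpha_{k}"] = v
        return df


def _model_groups(model):
    if isinstance(model, SphereModel):
        return model.groups
    return model.surface_groups


def _describe(model) -> str:
    if isinstance(model, SphereModel):
        return f"sphere R={model.radius} nm, eps_p={model.interior_dielectric}"
    if isinstance(model, CylinderModel):
        L = "inf" if model.is_infinite else f"{model.length:g}"
        return f"cylinder R={model.radius} nm, L={L} nm"
    return type(model).__name__


def _solve_for_charge(model, cond, mesh_scale=1.0, psi0=None):
    """(q_s, field) for sphere / infinite cylinder / finite cylinder."""
    if isinstance(model, SphereModel):
        fld = solve_sphere(model, cond, mesh_scale=mesh_scale, psi0=psi0)
        return net_charge(fld), fld
    if isinstance(model, CylinderModel):
        if model.is_infinite:
            fld = solve_cylinder_infinite(model, cond, mesh_scale=mesh_scale,
                                          psi0=psi0)
            return net_charge(fld), fld
        fld = solve_axisymmetric(model, cond, slit=None)
        return fem_object_charge(fld), fld
    raise InvalidParameterError(f"unsupported model {type(model)!r}")


def regulated_charge(
    model, cond: SolutionConditions, mesh_scale: float = 1.0
) -> ChargeReport:
    """Solve the regulated PB problem and report q_str, q_s and eta_g.

    For frozen (constant-charge) models q_s is the imposed charge and
    eta_g = 1 by construction.
    """
    if getattr(model, "frozen_charge", None) is not None:
        q = model.frozen_charge
        return ChargeReport(q, q, 1.0, cond, _describe(model),
                            {"frozen": True})
    q_str = structural_charge(_model_groups(model), cond.ph)
    if isinstance(model, CylinderModel) and model.is_infinite:
        q_str = sum(
            n * g.valence / (1.0 + 10.0 ** (g.valence * (cond.ph - g.pka)))
            for g, n in model.surface_groups.groups
        )  # per nm of contour
    q_s, fld = _solve_for_charge(model, cond, mesh_scale)
    eta = q_s / q_str if q_str != 0 else math.nan
    return ChargeReport(
        q_str, q_s, eta, cond, _describe(model),
        {"iterations": fld.iterations, "residual": fld.residual_norm,
         "n_nodes": len(fld.nodes)},
    )


def titration_curve(model, cond: SolutionConditions, ph_grid) -> TitrationCurve:
    """One regulated solve per pH, warm-started from the previous solution."""
    ph_grid = np.asarray(ph_grid, float)
    if np.any(np.diff(ph_grid) <= 0):
        raise InvalidParameterError("pH grid must be strictly increasing")
    qs = np.full(ph_grid.shape, np.nan)
    qstr = np.full(ph_grid.shape, np.nan)
    failed = np.zeros(ph_grid.shape, bool)
    groups = _model_groups(model)
    labels = [g.label or f"group{i}" for i, (g, _) in enumerate(groups.groups)]
    alpha = {lab: np.full(ph_grid.shape, np.nan) for lab in labels}
    psi0 = None
    for i, ph in enumerate(ph_grid):
        c = replace(cond, ph=float(ph))
        qstr[i] = structural_charge(groups, float(ph))
        try:
            q, fld = _solve_for_charge(model, c, psi0=psi0)
        except SolverError:
            failed[i] = True
            psi0 = None
            continue
        qs[i] = q
        if fld.geometry_tag.startswith("radial"):
            psi0 = fld.psi
        # per-group mean ionization from the group-resolved charge integrals
        for lab, (g, n) in zip(labels, groups.groups):
            if n == 0:
                continue
            single = _single_group_charge(model, fld, g, n, c)
            alpha[lab][i] = abs(single) / n
    return TitrationCurve(ph_grid, qs, qstr, alpha, failed)


def _single_group_charge(model, fld, group, count, cond):
    """Contribution of one group type to q_s of a converged field."""
    from .core import ionization_fraction

    if isinstance(model, SphereModel):
        problem = fld.payload["problem"]
        phi_s = model.phi_s(cond, group)
        rho = count / model.volume
        psi_a, psi_b = fld.psi[:-1], fld.psi[1:]
        total = 0.0
        for j, lay in enumerate(problem.layers):
            if lay.electrolyte:
                continue
            sel = problem.elem_layer == j
            aa = ionization_fraction(group, cond.ph, psi_a[sel], phi_s, model.phi_0)
            ab = ionization_fraction(group, cond.ph, psi_b[sel], phi_s, model.phi_0)
            total += group.valence * rho * np.sum(
                problem.m_a[sel] * aa + problem.m_b[sel] * ab
            )
        return 4.0 * math.pi * total
    # cylinders: surface alpha at the (uniform) surface potential
    if fld.geometry_tag == "radial_cylinder":
        psi_s = fld.psi[0]
    else:
        sn = fld.payload["surface_nodes"]
        w = fld.payload["surface_weights"]
        psi_s = float(np.sum(w * fld.psi[sn]) / np.sum(w))
    return count * group.valence * ionization_fraction(group, cond.ph, psi_s)


def isoelectric_point(curve: TitrationCurve) -> float:
    """pH at which q_s(pH) crosses zero (linear interpolation)."""
    ok = ~np.isnan(curve.q_s)
    ph, qs = curve.ph[ok], curve.q_s[ok]
    sign = np.sign(qs)
    crossings = np.nonzero(np.diff(sign) != 0)[0]
    crossings = [i for i in crossings if sign[i] != 0 or qs[i] == 0]
    if len(crossings) == 0:
        if np.any(qs == 0):
            return float(ph[np.argmin(np.abs(qs))])
        raise NotFoundError("titration curve does not cross zero on the grid")
    i = crossings[0]
    return float(ph[i] - qs[i] * (ph[i + 1] - ph[i]) / (qs[i + 1] - qs[i]))


def infer_interior_dielectric(
    model_template: SphereModel,
    cond: SolutionConditions,
    measured_charge: float,
    eps_bounds=(4.0, 78.5),
    rtol: float = 1e-4,
) -> float:
    """Root-find eps_p such that the regulated charge matches a measurement.

    q_s is monotone in eps_p for single-sign group sets (a lower interior
    dielectric raises both the internal potential magnitude and the Born
    penalty, discharging groups), so a bracketing root search is well posed.
    """
    lo, hi = eps_bounds

    def f(eps):
        m = replace(model_template, interior_dielectric=float(eps))
        return net_charge(solve_sphere(m, cond)) - measured_charge

    f_lo, f_hi = f(lo), f(hi)
    if f_lo * f_hi > 0:
        raise NotFoundError(
            "measured charge not attainable within eps bounds: "
            f"q_s({lo})={f_lo + measured_charge:.3f}, "
            f"q_s({hi})={f_hi + measured_charge:.3f}, target {measured_charge}"
        )
    return float(brentq(f, lo, hi, rtol=rtol))


def core_shell_pka(
    model: CoreShellModel,
    cond: SolutionConditions,
    ph_grid=None,
    shell_composition=None,
) -> float:
    """Apparent pKa of the single core group from its charge-vs-pH curve.

    Sweeps pH, integrates the charge inside the core and returns the pH at
    which it is half the fully ionized value (interpolated).  The shell
    background charge is held at ``model.shell_charge`` unless a
    ``shell_composition`` (IonizableGroupSet) is given, in which case the
    shell charge is recomputed per pH from the ideal titration of that
    composition.
    """
    if ph_grid is None:
        ph_grid = np.arange(1.0, 13.0 + 1e-9, 0.25)
    ph_grid = np.asarray(ph_grid, float)
    q_core = np.empty(ph_grid.shape)
    psi0 = None
    for i, ph in enumerate(ph_grid):
        c = replace(cond, ph=float(ph))
        q_shell = (
            structural_charge(shell_composition, float(ph))
            if shell_composition is not None
            else model.shell_charge
        )
        fld = solve_core_shell(model, c, shell_charge=q_shell, psi0=psi0)
        psi0 = fld.psi
        q_core[i] = core_charge(fld)
    half = 0.5 * model.core_group.valence  # half of the fully charged value
    # |q_core| rises from ~0 to ~1 across the titration; find the half crossing
    resid = q_core - half
    sign = np.sign(resid)
    crossings = np.nonzero(np.diff(sign) != 0)[0]
    if len(crossings) == 0:
        raise NotFoundError("half-ionization not bracketed by the pH grid")
    i = crossings[0]
    return float(
        ph_grid[i]
        - resid[i] * (ph_grid[i + 1] - ph_grid[i]) / (resid[i + 1] - resid[i])
    )
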