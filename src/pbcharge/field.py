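"""Field containers returned by the PB solvers.

A :class:`PBField` carries the mesh, the converged dimensionless potential
(psi~ = e psi / kBT), domain labels and convergence diagnostics.  Geometry
specific payload (lumped masses, layer descriptions, boundary data) is stored
by the solver that produced the field and consumed by the integration
routines (net charge, free energy) in the same module.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _field

import numpy as np


@dataclass
class PBField:
    geometry_tag: str  # "radial_sphere" | "radial_cylinder" | "slab" | "axisym"
    nodes: np.ndarray  # (N,) radii for 1-D, (N,2) (r,z) for axisymmetric
    psi: np.ndarray  # dimensionless potential per node
    converged: bool = False
    iterations: int = 0
    residual_norm: float = np.inf
    payload: dict = _field(default_factory=dict)

    @property
    def is_1d(self) -> bool:
        return self.nodes.ndim == 1

    def psi_at(self, x):
        """Linear interpolation of psi along the 1-D coordinate."""
        if not self.is_1d:
            raise ValueError("psi_at(x) is only defined for 1-D fields")
        return np.interp(x, self.nodes, self.psi)

    @property
    def surface_potential(self) -> float:
        """psi~ at the object surface (payload 'surface_radius')."""
        rs = self.payload.get("surface_radius")
        if rs is None:
            raise ValueError("field has no object surface")
        if self.is_1d:
            return float(self.psi_at(rs))
        raise ValueError("use axisym helpers for 2-D surface potentials")
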