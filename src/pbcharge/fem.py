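"""2-D axisymmetric finite-element solver for the nonlinear PB equation.

The geometry is a parallel-plate slit occupying 0 <= z <= 2h, 0 <= r <= rmax
in cylindrical coordinates (axis of symmetry r = 0), optionally containing a
constant- or regulated-charge object (sphere or finite cylinder) centred at
the mid-plane z = h.  Objects are electrolyte cavities carrying surface
charge; the electrolyte obeys  laplace(psi) = kappa^2 sinh(psi)  with Neumann
data  d psi/dn = -4 pi lB sigma~  on charged surfaces and natural zero flux
on the outer truncation and the axis.

Meshes are built so that the *same* triangulation serves both the
object-present problem (hole triangles deactivated) and the object-absent
problem (hole triangles filled with electrolyte): free-energy differences
between the two then benefit from exact cancellation of discretization error
away from the hole region.

P1 triangles, lumped masses for the sinh term, damped Newton with
backtracking; sparse LU from scipy at each iteration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import Delaunay, cKDTree

from .core import SolutionConditions, ionization_fraction
from .exceptions import GeometryError, SolverError
from .field import PBField
from .models import CylinderModel, SphereModel, SlitGeometry
from .radial import graded_band

__all__ = [
    "MeshControls",
    "AxisymMesh",
    "build_slit_mesh",
    "solve_slit",
    "solve_axisymmetric",
    "free_energy",
    "electrolyte_ion_charge",
    "interpolate",
    "write_vtu",
]


@dataclass(frozen=True)
class MeshControls:
    """Grading parameters for the axisymmetric meshes (all lengths nm)."""

    surface_layer: float = 0.05  # first element at charged object surfaces
    growth: float = 1.35
    far_fraction: float = 0.18  # far spacing as a fraction of the Debye length
    wall_fraction: float = 0.06  # first layer at the walls (fraction of kappa^-1)
    scale: float = 1.0  # multiplies every spacing (grid-convergence knob)

    def scaled(self, factor: float) -> "MeshControls":
        return replace(self, scale=self.scale * factor)


@dataclass
class AxisymMesh:
    """Shared triangulation of the slit box with an optional object hole.

    ``planar=False``: axisymmetric coordinates (r, z), volume measure
    2 pi r dr dz (sphere or axis-aligned finite cylinder at the mid-plane).
    ``planar=True``: Cartesian cross-section (x, z) of an infinite cylinder
    lying parallel to the walls; x >= 0 half-plane with mirror symmetry, all
    integrals per unit length of the cylinder (measure 2 dx dz).
    """

    nodes: np.ndarray  # (N, 2) columns (r|x, z)
    tris: np.ndarray  # (M, 3)
    hole_tris: np.ndarray  # (M,) bool: triangle lies inside the object
    rmax: float
    height: float  # 2h
    object_kind: str | None = None  # "sphere" | "cylinder" | None
    planar: bool = False

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def angular_factor(self) -> float:
        """2 pi for solids of revolution, 2 for the mirrored planar half-plane."""
        return 2.0 if self.planar else 2.0 * math.pi


# ---------------------------------------------------------------------------
# mesh construction
# ---------------------------------------------------------------------------

def _band_around(center, half, h0, growth, hmax, lo, hi):
    """Breakpoints refined on both sides of the interval center +- half."""
    a, b = center - half, center + half
    left = a - (graded_band(0.0, a - lo, h0, growth, hmax) if a > lo else np.array([0.0]))
    right = b + (graded_band(0.0, hi - b, h0, growth, hmax) if b < hi else np.array([0.0]))
    inner = np.array([a, b]) if half > 0 else np.array([center])
    return np.concatenate([left, right, inner])


def _dedup(x, tol=1e-9):
    x = np.sort(np.asarray(x, float))
    keep = np.concatenate([[True], np.diff(x) > tol])
    return x[keep]


def _tensor_tris(rs, zs):
    """Structured triangulation of the tensor grid rs x zs."""
    nr, nz = len(rs), len(zs)
    rr, zz = np.meshgrid(rs, zs, indexing="ij")
    nodes = np.column_stack([rr.ravel(), zz.ravel()])
    idx = np.arange(nr * nz).reshape(nr, nz)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    tris = np.concatenate([np.column_stack([a, b, c]), np.column_stack([a, c, d])])
    return nodes, tris


def build_slit_mesh(
    model: SphereModel | CylinderModel | None,
    cond: SolutionConditions,
    slit: SlitGeometry,
    controls: MeshControls = MeshControls(),
) -> AxisymMesh:
    """Triangulate the slit box, marking object-interior triangles.

    ``model=None`` builds an empty-slit tensor mesh.  Spheres use a hybrid
    Delaunay mesh (polar rings around the surface stitched to a graded tensor
    background); finite cylinders use a pure tensor mesh aligned with the
    cylinder faces.
    """
    kappa = cond.kappa
    ld = 1.0 / kappa
    h = slit.half_height
    H = 2.0 * h
    rmax = slit.lateral_extent
    s = controls.scale
    far = controls.far_fraction * ld * s
    wall0 = controls.wall_fraction * ld * s
    g = 1.0 + (controls.growth - 1.0) * s
    surf0 = controls.surface_layer * s

    def wall_lines():
        zl = graded_band(0.0, h, wall0, g, far)
        return np.concatenate([zl, H - zl])

    if model is None:
        rs = _dedup(graded_band(0.0, rmax, far, 1.0, far))
        zs = _dedup(wall_lines())
        nodes, tris = _tensor_tris(rs, zs)
        return AxisymMesh(nodes, tris, np.zeros(len(tris), bool), rmax, H, None)

    if isinstance(model, CylinderModel) and model.is_infinite:
        # cross-section of an infinite cylinder parallel to the walls
        return _circle_mesh(model.radius, cond, slit, controls, planar=True,
                            kind="cylinder")

    if isinstance(model, CylinderModel):
        R, L = model.radius, model.length
        z1, z2 = h - L / 2.0, h + L / 2.0
        if z1 <= 0:
            raise GeometryError("cylinder does not fit in the slit")
        # radial lines: inside the hole coarse, boundary layers at r = R
        r_in = R - graded_band(0.0, R, surf0, g, max(R / 4.0, surf0))
        r_out = R + graded_band(0.0, rmax - R, surf0, g, far)
        rs = _dedup(np.concatenate([r_in, r_out]))
        # z lines: refined at the cap faces and the walls
        z_caps = _band_around((z1 + z2) / 2.0, L / 2.0, surf0, g, far, 0.0, H)
        z_inside = z1 + graded_band(0.0, L, surf0, g, max(L / 6.0, surf0))
        zs = _dedup(np.concatenate([wall_lines(), z_caps, z_inside]))
        nodes, tris = _tensor_tris(rs, zs)
        cent = nodes[tris].mean(axis=1)
        hole = (
            (cent[:, 0] < R) & (cent[:, 1] > z1) & (cent[:, 1] < z2)
        )
        return AxisymMesh(nodes, tris, hole, rmax, H, "cylinder")

    if isinstance(model, SphereModel):
        return _circle_mesh(model.radius, cond, slit, controls, planar=False,
                            kind="sphere")

    raise GeometryError(f"cannot mesh object of type {type(model)!r}")


def _circle_mesh(R, cond, slit, controls, planar, kind):
    """Delaunay mesh of the slit box with a circular hole on the symmetry axis."""
    kappa = cond.kappa
    ld = 1.0 / kappa
    h = slit.half_height
    H = 2.0 * h
    rmax = slit.lateral_extent
    s = controls.scale
    far = controls.far_fraction * ld * s
    wall0 = controls.wall_fraction * ld * s
    g = 1.0 + (controls.growth - 1.0) * s
    surf0 = controls.surface_layer * s

    def wall_lines():
        zl = graded_band(0.0, h, wall0, g, far)
        return np.concatenate([zl, H - zl])

    if h <= R:
        raise GeometryError("object does not fit in the slit")
    # polar rings hugging the surface, outwards and inwards
    t_out = graded_band(0.0, min(6.0 * ld, h - R, rmax - R), surf0, g, far)[1:]
    t_in = graded_band(0.0, 0.6 * R, surf0, g, max(R / 5.0, surf0))[1:]
    radii = np.concatenate([[R], R + t_out, R - t_in])
    pts = []
    for rad in radii:
        n_t = max(12, int(math.pi * rad / min(
            surf0 * (1 + abs(rad - R) / (2 * surf0)), far)))
        theta = np.linspace(0.0, math.pi, n_t + 1)
        pts.append(
            np.column_stack([rad * np.sin(theta), h + rad * np.cos(theta)])
        )
    ring_pts = np.vstack(pts)
    # coarse core of the hole
    core = graded_band(0.0, R - t_in[-1] if len(t_in) else R, far / 2, 1.0, far / 2)
    core_r, core_z = np.meshgrid(core, h + np.concatenate([-core[::-1], core[1:]]))
    core_pts = np.column_stack([core_r.ravel(), core_z.ravel()])
    core_pts = core_pts[
        np.hypot(core_pts[:, 0], core_pts[:, 1] - h) < (R - (t_in[-1] if len(t_in) else 0)) * 0.92
    ]
    # background tensor grid
    rs = _dedup(graded_band(0.0, rmax, far / 1.5, 1.0, far / 1.5))
    zs = _dedup(wall_lines())
    bg_r, bg_z = np.meshgrid(rs, zs, indexing="ij")
    bg = np.column_stack([bg_r.ravel(), bg_z.ravel()])
    # drop background points overlapping the ring/core region
    r_outer_ring = R + (t_out[-1] if len(t_out) else 0.0)
    dist = np.hypot(bg[:, 0], bg[:, 1] - h)
    keep = dist > r_outer_ring + 0.35 * far
    # but never drop the box boundary
    on_box = (
        (bg[:, 0] < 1e-9) | (bg[:, 0] > rmax - 1e-9)
        | (bg[:, 1] < 1e-9) | (bg[:, 1] > H - 1e-9)
    )
    bg = bg[keep | on_box]
    allpts = np.vstack([ring_pts, core_pts, bg])
    # remove near-duplicates (keeps the first occurrence: ring points win)
    tree = cKDTree(allpts)
    pairs = tree.query_pairs(1e-6)
    drop = {max(i, j) for i, j in pairs}
    allpts = allpts[[i for i in range(len(allpts)) if i not in drop]]
    tri = Delaunay(allpts)
    tris = tri.simplices.copy()
    nodes = tri.points
    # discard degenerate slivers
    d1 = nodes[tris[:, 1]] - nodes[tris[:, 0]]
    d2 = nodes[tris[:, 2]] - nodes[tris[:, 0]]
    area2 = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    good = np.abs(area2) > 1e-12
    tris = tris[good]
    cent = nodes[tris].mean(axis=1)
    hole = np.hypot(cent[:, 0], cent[:, 1] - h) < R
    return AxisymMesh(nodes, tris, hole, rmax, H, kind, planar=planar)


def sphere_pair_mesh(
    R: float,
    separation: float,
    cond: SolutionConditions,
    controls: MeshControls = MeshControls(),
    margin_debye: float = 8.0,
) -> AxisymMesh:
    """Two equal spheres on the symmetry axis, centre-to-centre ``separation``.

    Used for the far-field screened-Coulomb consistency check: the box is
    uncharged (natural zero flux) and extends ``margin_debye`` Debye lengths
    beyond each sphere.  Ring layouts around both spheres are identical, so
    free-energy differences between separations cancel the dominant
    surface-layer discretization error.
    """
    ld = cond.debye_length
    s = controls.scale
    far = controls.far_fraction * ld * s
    g = 1.0 + (controls.growth - 1.0) * s
    surf0 = controls.surface_layer * s
    margin = R + margin_debye * ld
    Z = separation + 2.0 * margin
    rmax = margin
    centers = [Z / 2.0 - separation / 2.0, Z / 2.0 + separation / 2.0]
    if separation <= 2.0 * R:
        raise GeometryError("spheres overlap")

    t_out = graded_band(0.0, min(4.0 * ld, (separation - 2 * R) / 2.5), surf0, g, far)[1:]
    t_in = graded_band(0.0, 0.6 * R, surf0, g, max(R / 5.0, surf0))[1:]
    radii = np.concatenate([[R], R + t_out, R - t_in])
    pts = []
    for zc in centers:
        for rad in radii:
            n_t = max(12, int(math.pi * rad / min(
                surf0 * (1 + abs(rad - R) / (2 * surf0)), far)))
            theta = np.linspace(0.0, math.pi, n_t + 1)
            pts.append(np.column_stack([rad * np.sin(theta),
                                        zc + rad * np.cos(theta)]))
        core = graded_band(0.0, R - (t_in[-1] if len(t_in) else 0), far / 2,
                           1.0, far / 2)
        cr, cz = np.meshgrid(core, zc + np.concatenate([-core[::-1], core[1:]]))
        cp = np.column_stack([cr.ravel(), cz.ravel()])
        pts.append(cp[np.hypot(cp[:, 0], cp[:, 1] - zc)
                      < (R - (t_in[-1] if len(t_in) else 0)) * 0.92])
    ring_pts = np.vstack(pts)

    rs = _dedup(graded_band(0.0, rmax, far / 1.5, 1.0, far / 1.5))
    zs = _dedup(graded_band(0.0, Z, far / 1.5, 1.0, far / 1.5))
    bg_r, bg_z = np.meshgrid(rs, zs, indexing="ij")
    bg = np.column_stack([bg_r.ravel(), bg_z.ravel()])
    r_ring = R + (t_out[-1] if len(t_out) else 0.0)
    dist = np.minimum(
        np.hypot(bg[:, 0], bg[:, 1] - centers[0]),
        np.hypot(bg[:, 0], bg[:, 1] - centers[1]),
    )
    on_box = ((bg[:, 0] < 1e-9) | (bg[:, 0] > rmax - 1e-9)
              | (bg[:, 1] < 1e-9) | (bg[:, 1] > Z - 1e-9))
    bg = bg[(dist > r_ring + 0.35 * far) | on_box]
    allpts = np.vstack([ring_pts, bg])
    tree = cKDTree(allpts)
    drop = {max(i, j) for i, j in tree.query_pairs(1e-6)}
    allpts = allpts[[i for i in range(len(allpts)) if i not in drop]]
    tri = Delaunay(allpts)
    nodes, tris = tri.points, tri.simplices.copy()
    d1 = nodes[tris[:, 1]] - nodes[tris[:, 0]]
    d2 = nodes[tris[:, 2]] - nodes[tris[:, 0]]
    good = np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]) > 1e-12
    tris = tris[good]
    cent = nodes[tris].mean(axis=1)
    hole = (np.hypot(cent[:, 0], cent[:, 1] - centers[0]) < R) | (
        np.hypot(cent[:, 0], cent[:, 1] - centers[1]) < R)
    return AxisymMesh(nodes, tris, hole, rmax, Z, "sphere_pair")


def solve_sphere_pair(
    R: float,
    charge_each: float,
    separation: float,
    cond: SolutionConditions,
    controls: MeshControls = MeshControls(),
) -> PBField:
    """Two like-charged spheres on the axis in an uncharged box."""
    mesh = sphere_pair_mesh(R, separation, cond, controls)
    return solve_slit(mesh, cond, object_charge=2.0 * charge_each,
                      wall_sigma=0.0, with_object=True)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

class _Assembly:
    def __init__(self, mesh: AxisymMesh, active: np.ndarray):
        nodes, tris = mesh.nodes, mesh.tris[active]
        self.planar = mesh.planar
        r = np.ones(len(nodes)) if mesh.planar else nodes[:, 0]
        p0, p1, p2 = nodes[tris[:, 0]], nodes[tris[:, 1]], nodes[tris[:, 2]]
        d1, d2 = p1 - p0, p2 - p0
        det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
        area = 0.5 * np.abs(det)
        if np.any(area <= 0):
            raise GeometryError("mesh contains degenerate triangles")
        # P1 shape gradients
        b = np.stack([p1[:, 1] - p2[:, 1], p2[:, 1] - p0[:, 1], p0[:, 1] - p1[:, 1]], axis=1)
        c = np.stack([p2[:, 0] - p1[:, 0], p0[:, 0] - p2[:, 0], p1[:, 0] - p0[:, 0]], axis=1)
        grad = np.stack([b, c], axis=2) / det[:, None, None]  # (M,3,2)
        rbar = (r[tris[:, 0]] + r[tris[:, 1]] + r[tris[:, 2]]) / 3.0
        # stiffness: sum_e rbar * area * grad_i . grad_j
        ke = np.einsum("eid,ejd->eij", grad, grad) * (rbar * area)[:, None, None]
        ii = np.repeat(tris, 3, axis=1).ravel()
        jj = np.tile(tris, (1, 3)).ravel()
        self.K = sp.csc_matrix(
            (ke.ravel(), (ii, jj)), shape=(len(nodes), len(nodes))
        )
        # lumped axisymmetric masses: int r phi_i dA = A (2 r_i + r_j + r_k) / 12
        M = np.zeros(len(nodes))
        for loc in range(3):
            ri = r[tris[:, loc]]
            rsum = r[tris[:, 0]] + r[tris[:, 1]] + r[tris[:, 2]]
            np.add.at(M, tris[:, loc], area * (ri + rsum) / 12.0)
        self.M = M
        self.tris = tris
        self.area = area
        self.rbar = rbar
        self.grad = grad
        self.nodes = nodes

    def boundary_edges(self):
        """Edges belonging to exactly one active triangle, as (a, b) pairs."""
        e = np.concatenate([
            self.tris[:, [0, 1]], self.tris[:, [1, 2]], self.tris[:, [2, 0]]
        ])
        key = np.sort(e, axis=1)
        uniq, counts = np.unique(key, axis=0, return_counts=True)
        return uniq[counts == 1]


def _classify_edges(mesh: AxisymMesh, edges: np.ndarray):
    """Split boundary edges into wall / axis / outer / object-surface sets."""
    nodes = mesh.nodes
    mids = 0.5 * (nodes[edges[:, 0]] + nodes[edges[:, 1]])
    tol = 1e-7 * max(mesh.rmax, mesh.height)
    on_wall = (mids[:, 1] < tol) | (mids[:, 1] > mesh.height - tol)
    on_axis = mids[:, 0] < tol
    on_outer = mids[:, 0] > mesh.rmax - tol
    surface = ~(on_wall | on_axis | on_outer)
    return edges[on_wall], edges[surface]


def _edge_weights(nodes, edges, planar=False):
    """Boundary quadrature int w phi ds per edge endpoint (w = r, or 1 planar)."""
    a, b = nodes[edges[:, 0]], nodes[edges[:, 1]]
    length = np.hypot(*(b - a).T)
    if planar:
        wa = wb = 0.5 * length
    else:
        ra, rb = a[:, 0], b[:, 0]
        wa = length * (2.0 * ra + rb) / 6.0
        wb = length * (ra + 2.0 * rb) / 6.0
    return wa, wb, length


def surface_measure(nodes, edges, planar=False) -> float:
    """Discrete measure of the surface traced by ``edges``.

    Axisymmetric: area of the surface of revolution (nm^2).  Planar: contour
    length of the full (mirrored) cross-section per unit cylinder length (nm).
    """
    wa, wb, _ = _edge_weights(nodes, edges, planar)
    ang = 2.0 if planar else 2.0 * math.pi
    return ang * float(np.sum(wa + wb))


# ---------------------------------------------------------------------------
# solve
# ---------------------------------------------------------------------------

def solve_slit(
    mesh: AxisymMesh,
    cond: SolutionConditions,
    object_charge: float | None = None,
    wall_sigma: float = 0.0,
    regulated_groups=None,
    with_object: bool | None = None,
    psi0=None,
    tol: float = 1e-9,
    max_iter: int = 80,
) -> PBField:
    """Solve the nonlinear PB problem on a slit mesh.

    ``object_charge``: total constant charge (e) spread uniformly over the
    discrete object surface; ``regulated_groups`` instead places an
    IonizableGroupSet (total counts) on the surface with self-consistent
    ionization.  ``with_object=False`` fills the hole with electrolyte (the
    empty-slit reference on the identical triangulation).
    """
    if with_object is None:
        with_object = mesh.object_kind is not None and (
            object_charge is not None or regulated_groups is not None
        )
    active = ~mesh.hole_tris if with_object else np.ones(len(mesh.tris), bool)
    asm = _Assembly(mesh, active)
    lb = cond.bjerrum_length
    kappa2 = cond.kappa**2

    edges = asm.boundary_edges()
    wall_edges, surf_edges = _classify_edges(mesh, edges)

    n = mesh.n_nodes
    b = np.zeros(n)
    if wall_sigma != 0.0:
        wa, wb, _ = _edge_weights(mesh.nodes, wall_edges, mesh.planar)
        coef = 4.0 * math.pi * lb * wall_sigma
        np.add.at(b, wall_edges[:, 0], coef * wa)
        np.add.at(b, wall_edges[:, 1], coef * wb)

    surf_nodes = None
    surf_weight = None
    sigma_uniform = 0.0
    area_disc = 0.0
    if with_object and len(surf_edges):
        area_disc = surface_measure(mesh.nodes, surf_edges, mesh.planar)
        wa, wb, _ = _edge_weights(mesh.nodes, surf_edges, mesh.planar)
        w = np.zeros(n)
        np.add.at(w, surf_edges[:, 0], wa)
        np.add.at(w, surf_edges[:, 1], wb)
        surf_nodes = np.nonzero(w)[0]
        surf_weight = w[surf_nodes]
        if object_charge is not None:
            sigma_uniform = object_charge / area_disc
            b[surf_nodes] += 4.0 * math.pi * lb * sigma_uniform * surf_weight

    groups_per_area = None
    if regulated_groups is not None:
        if surf_nodes is None:
            raise GeometryError("regulated surface requires an object in the mesh")
        groups_per_area = [(g, cnt / area_disc) for g, cnt in regulated_groups.groups]

    # masses only over active triangles; isolated (hole-interior) nodes of the
    # object-present problem are pinned to zero through the identity rows below
    M = asm.M
    free = M > 0
    K = asm.K
    ph = cond.ph

    def nonlinear(psi):
        s = np.clip(psi, -500, 500)
        N = kappa2 * M * np.sinh(s)
        dN = kappa2 * M * np.cosh(s)
        if groups_per_area is not None:
            sig = np.zeros(len(surf_nodes))
            dsig = np.zeros(len(surf_nodes))
            for g, dens in groups_per_area:
                a = ionization_fraction(g, ph, psi[surf_nodes])
                sig += g.valence * dens * a
                dsig += -dens * a * (1.0 - a)
            N[surf_nodes] -= 4.0 * math.pi * lb * sig * surf_weight
            dN[surf_nodes] -= 4.0 * math.pi * lb * dsig * surf_weight
        return N, dN

    psi = np.zeros(n) if psi0 is None else np.array(psi0, float)
    history = []
    ok = False
    it = 0
    rnorm = np.inf
    ident = sp.diags((~free).astype(float))
    for it in range(1, max_iter + 1):
        N, dN = nonlinear(psi)
        res = K @ psi + N - b
        res[~free] = psi[~free]
        rnorm = float(np.max(np.abs(res)))
        history.append(rnorm)
        J = K + sp.diags(dN) + ident
        step = spla.spsolve(J.tocsc(), -res)
        smax = float(np.max(np.abs(step)))
        if smax > 8.0:
            step *= 8.0 / smax
        lam = 1.0
        for _ in range(40):
            trial = psi + lam * step
            Nt, _ = nonlinear(trial)
            rt = K @ trial + Nt - b
            rt[~free] = trial[~free]
            tnorm = float(np.max(np.abs(rt)))
            if tnorm < rnorm or smax * lam < tol:
                break
            lam *= 0.5
        psi = psi + lam * step
        if smax * lam < tol:
            ok = True
            rnorm = tnorm
            break
    if not ok:
        raise SolverError(
            f"axisymmetric solve failed to converge (residual {rnorm:.3e})", history
        )

    payload = {
        "mesh": mesh,
        "assembly": asm,
        "cond": cond,
        "with_object": with_object,
        "wall_sigma": wall_sigma,
        "wall_edges": wall_edges,
        "surface_edges": surf_edges if with_object else np.empty((0, 2), int),
        "surface_nodes": surf_nodes,
        "surface_weights": surf_weight,
        "object_sigma": sigma_uniform,
        "object_area": area_disc,
        "groups_per_area": groups_per_area,
    }
    if object_charge is not None:
        payload["frozen_charge"] = object_charge
    return PBField(
        geometry_tag="axisym",
        nodes=mesh.nodes,
        psi=psi,
        converged=True,
        iterations=it,
        residual_norm=rnorm,
        payload=payload,
    )


def solve_axisymmetric(
    model: SphereModel | CylinderModel,
    cond: SolutionConditions,
    slit: SlitGeometry | None = None,
    controls: MeshControls = MeshControls(),
    wall_sigma: float | None = None,
    psi0=None,
) -> PBField:
    """Mesh and solve a finite object, optionally inside a charged slit.

    With ``slit=None`` the object sits in an uncharged box extending ten Debye
    lengths from every surface (an isolated-molecule solve).
    """
    ld = cond.debye_length
    if slit is None:
        if isinstance(model, CylinderModel) and not model.is_infinite:
            half = model.length / 2.0
        else:
            half = model.radius
        slit = SlitGeometry(
            half_height=half + 10.0 * ld,
            wall_surface_charge=0.0,
            lateral_extent=model.radius + 10.0 * ld,
        )
    sigma = slit.wall_surface_charge if wall_sigma is None else wall_sigma
    mesh = build_slit_mesh(model, cond, slit, controls)
    if model.frozen_charge is not None:
        return solve_slit(mesh, cond, object_charge=model.frozen_charge,
                          wall_sigma=sigma, psi0=psi0)
    groups = (
        model.surface_groups if isinstance(model, CylinderModel) else model.groups
    )
    if isinstance(model, SphereModel):
        warnings.warn(
            "axisymmetric spheres are treated as surface-charge cavities; "
            "use radial.solve_sphere for volume-regulated interiors"
        )
    return solve_slit(mesh, cond, regulated_groups=groups, wall_sigma=sigma,
                      psi0=psi0)


# ---------------------------------------------------------------------------
# integrals and diagnostics
# ---------------------------------------------------------------------------

def free_energy(field: PBField, cond: SolutionConditions | None = None) -> float:
    """Electrostatic free energy (kBT): field-gradient plus ionic term.

    F = int [ |grad psi|^2 / (8 pi lB) + (kappa^2/4 pi lB)(psi sinh psi
    - cosh psi + 1) ] dV over the electrolyte.  Objects are cavities, so the
    gradient term has no interior contribution.
    """
    if not field.converged:
        raise SolverError("refusing to integrate an unconverged field")
    cond = cond or field.payload["cond"]
    asm = field.payload["assembly"]
    lb = cond.bjerrum_length
    kappa2 = cond.kappa**2
    psi_tri = field.psi[asm.tris]
    g = np.einsum("eid,ei->ed", asm.grad, psi_tri)
    f_grad = np.sum((g**2).sum(axis=1) * asm.rbar * asm.area) / (8.0 * math.pi * lb)
    s = np.clip(field.psi, -500, 500)
    entro = s * np.sinh(s) - np.cosh(s) + 1.0
    f_ion = kappa2 / (4.0 * math.pi * lb) * np.sum(asm.M * entro)
    ang = field.payload["mesh"].angular_factor
    return ang * (f_grad + f_ion)


def electrolyte_ion_charge(field: PBField) -> float:
    """Total mobile-ion charge in the electrolyte (e)."""
    cond = field.payload["cond"]
    asm = field.payload["assembly"]
    s = np.clip(field.psi, -500, 500)
    coef = -cond.kappa**2 / (4.0 * math.pi * cond.bjerrum_length)
    ang = field.payload["mesh"].angular_factor
    return ang * coef * float(np.sum(asm.M * np.sinh(s)))


def wall_charge(field: PBField) -> float:
    """Total charge on both walls (e), from the discrete wall measure."""
    mesh = field.payload["mesh"]
    area = surface_measure(field.nodes, field.payload["wall_edges"], mesh.planar)
    return field.payload["wall_sigma"] * area


def object_charge(field: PBField) -> float:
    """Total charge on the object surface (e)."""
    if not field.payload["with_object"]:
        return 0.0
    if "frozen_charge" in field.payload:
        return field.payload["frozen_charge"]
    cond = field.payload["cond"]
    sn = field.payload["surface_nodes"]
    w = field.payload["surface_weights"]
    ang = field.payload["mesh"].angular_factor
    total = 0.0
    for g, dens in field.payload["groups_per_area"]:
        a = ionization_fraction(g, cond.ph, field.psi[sn])
        total += float(np.sum(g.valence * dens * a * w)) * ang
    return total


def interpolate(field: PBField, points: np.ndarray) -> np.ndarray:
    """Linear interpolation of psi at (r, z) points (Delaunay-based)."""
    from scipy.interpolate import LinearNDInterpolator

    interp = field.payload.get("_interp")
    if interp is None:
        interp = LinearNDInterpolator(field.nodes, field.psi)
        field.payload["_interp"] = interp
    vals = interp(points)
    if np.any(np.isnan(vals)):
        from scipy.interpolate import NearestNDInterpolator

        nearest = NearestNDInterpolator(field.nodes, field.psi)
        bad = np.isnan(vals)
        vals[bad] = nearest(points[bad])
    return vals


def write_vtu(field: PBField, path: str) -> None:
    """Dump an axisymmetric field as ASCII VTU for visual inspection."""
    asm = field.payload["assembly"]
    nodes, tris = asm.nodes, asm.tris
    with open(path, "w") as fh:
        fh.write('<?xml version="1.0"?>\n')
        fh.write('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n')
        fh.write(f'<UnstructuredGrid><Piece NumberOfPoints="{len(nodes)}" NumberOfCells="{len(tris)}">\n')
        fh.write('<Points><DataArray type="Float64" NumberOfComponents="3" format="ascii">\n')
        for r, z in nodes:
            fh.write(f"{r} {z} 0\n")
        fh.write('</DataArray></Points>\n<Cells>\n')
        fh.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n')
        for t in tris:
            fh.write(f"{t[0]} {t[1]} {t[2]}\n")
        fh.write('</DataArray>\n<DataArray type="Int64" Name="offsets" format="ascii">\n')
        for i in range(1, len(tris) + 1):
            fh.write(f"{3 * i}\n")
        fh.write('</DataArray>\n<DataArray type="UInt8" Name="types" format="ascii">\n')
        fh.write("5\n" * len(tris))
        fh.write('</DataArray>\n</Cells>\n<PointData Scalars="psi">\n')
        fh.write('<DataArray type="Float64" Name="psi" format="ascii">\n')
        for v in field.psi:
            fh.write(f"{v}\n")
        fh.write('</DataArray></PointData>\n</Piece></UnstructuredGrid></VTKFile>\n')
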