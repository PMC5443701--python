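# Methods

## Model

A molecule is a continuum dielectric body in a 1:1 electrolyte of bulk
concentration c (mol/L), solvent dielectric ε_m = 78.5 (water, 25 °C).
Potentials are dimensionless (ψ = eΨ/k_BT), lengths in nm, charges in e,
energies in k_BT. Physical constants are CODATA 2018; with these,
l_B,w = 0.714 nm and κ⁻¹ = 0.962 nm at 100 mM (sometimes quoted rounded to
0.9 nm elsewhere; we do not adjust constants).

**Globular molecules** are spheres of radius R and interior dielectric ε_p
carrying a uniform volume density of ionizable groups. The interior is
transparent to protons (chemistry couples to the local potential) but
impervious to salt ions: interior Poisson, exterior nonlinear PB. The
interface enforces continuity of ψ and of ε ∂ψ/∂n; the outer boundary at
R + 10 κ⁻¹ is zero-flux (electroneutrality). Ionization follows

α = 1/(1 + 10^{z(pH−pK)} exp(zψ + φ_s + φ_0)),

with the Born penalty φ_s = p (l_B,m/2r_A)(ε_m/ε_p − 1), clamped at 0, the
default r_A = 0.25 nm, attenuation p = 1 and φ_0 = 0. A positive potential
ionizes acids and discharges bases; the self-generated negative potential of
an acidic molecule is what suppresses its own ionization.

**Linear polyelectrolytes** are rigid hollow cylinders (protein chains
D = 0.5 nm at 0.38 nm/residue; ssDNA D = 1 nm and dsDNA D = 2 nm at
0.34 nm/base(-pair), 2 phosphates per bp) with the charge as a regulating
uniform surface density; no interior domain exists, so ε_p is not a
parameter. Group inventories derive from sequence via a shipped pKa table
(Glu 4.3, Lys 10.4, Cys 8.2 are the load-bearing nominal values; Asp 4.0,
His 6.0, Arg 12.0, Tyr 10.0, termini 8.0/3.6 and phosphate 2.0 are
conventional defaults, all overridable). Protons are excluded from the
screening (κ from salt only), valid for pH ≈ 3–11 at the salt
concentrations considered.

## Numerics

*1-D radial solver* (spheres, layered spheres, infinite cylinders, planar
slabs): P1 finite elements on graded grids (surface boundary layer ~0.01 nm
growing geometrically to ~κ⁻¹/6), measure r^d dr with d = 2, 1, 0. The
regulation source is folded into the nonlinear residual; damped Newton with
backtracking converges in ≤ ~10 iterations; tolerance 10⁻⁹ on the update
norm. A damped Picard iteration (freeze the regulated density, solve, relax)
is kept as an independent cross-check and agrees with Newton to < 10⁻⁴.
Grid halving changes q_s and F by < 0.1%; extending the domain from 10 to
15 κ⁻¹ changes q_s by < 0.5%.

*2-D solver*: triangulated slit domains, P1 elements, lumped masses for the
sinh term (axisymmetric weight ∫ r φ dA, planar ∫ φ dA), surface charge as
Neumann data with exact total-charge normalization on the discrete surface,
damped Newton with an 8 k_BT/e trust radius. Finite cylinders use tensor
meshes aligned with the faces; spheres (and infinite-cylinder cross
sections) use Delaunay meshes of polar rings stitched to a graded tensor
background. Mesh defaults: 0.05 nm first layer at charged object surfaces,
growth 1.35, far spacing 0.18 κ⁻¹, wall layer 0.06 κ⁻¹; the Table-I-scale
runs use ~6–10k nodes and solve in ~1 s. Halving all length scales moves
the benchmark effective charges by < 0.5%.

*Free energy*: gradient term with the local dielectric plus the ionic term
over the electrolyte, evaluated with the same quadrature as the residual so
that energy differences between runs on a shared mesh cancel discretization
error.

## Effective-charge protocol

The object sits at the mid-plane of a slit of half-height h with
like-charged walls; the gap is κz* = 4 (insensitive over κz* ≈ 3–5, < 5%
variation), the wall charge is chosen by the Gouy–Chapman relation to give
an isolated-wall potential of magnitude 0.5 k_BT/e (halving it changes
q_eff by < 5%), and the lateral truncation is R + 10 κ⁻¹.

F_os = F(object + charged walls) − F(object + uncharged walls) − F(empty
charged slit). The first two solves share one triangulation (the hole
deactivated); the empty-slit solve fills the hole of the *same*
triangulation, so both the object self-energy and the wall self-energy
cancel together with their discretization errors. This realizes the
reference state F(z*→∞) = F(isolated object) + F(empty slit) up to
O(e^{−2κz*}) wall-image corrections (≈ 10⁻⁴ relative at κz* = 4) while
keeping a tiny interaction energy (often < 1 k_BT) accurate against
self-energies of hundreds of k_BT. ⟨ψ′(s)⟩ is the area-weighted mean of the
empty-slit potential over ≥ 400 points on the virtual object surface.
q_eff = F_os/⟨ψ′⟩; regulation is frozen at the free-solution q_s before the
constant-charge slit runs.

**Geometry of cylinders.** Finite molecules (the DNA fragments) stand on
the symmetry axis, caps toward the walls — the only axisymmetric placement —
and at 1 mM (κL ≈ 2) they are quasi-point-like, so the extraction is
well-conditioned. The *infinite-cylinder* limit used for the condensation
comparison cannot be reached that way (the interaction becomes
cap-dominated); an infinite cylinder lying parallel to the walls reduces to
a planar cross-section problem per unit length, which is how the
`renormalization_sweep` is computed. In the weak-charge limit this
construction returns η_n = 1 to ~1% at κR = 0.1, and it agrees with an
independent far-field potential-matching extraction (fit of A·K₀(κr) to the
1-D nonlinear cylinder solution) to < 1% at every line-charge strength
tested.

**Known bias.** ⟨ψ′⟩ is defined on the slit *without* the object, but F_os
contains the interaction of the field with the object's ion-free cavity;
the resulting overestimate of η_n is O((κR)²) — ~1.5% at κR = 0.1, ~5%
(sphere) to ~9–16% (extended cylinder) at κR = 0.5. This is intrinsic to
the definition, not a numerical artifact.

**Manning comparison.** At κR = 0.1 the computed η_n exceeds the Manning
fraction 1/ξ by ~1% at ξ = 2 rising to ~16% at ξ = 6 (rms ≈ 12% over
ξ ∈ {2, 3, 4.2, 5, 6}). The excess is physical: the PB effective charge of
a cylinder converges to the condensation limit only logarithmically in κR,
and boundary-layer theories place the finite-κR effective charge above 1/ξ
exactly as observed. The sweep's study condition κR = 0.1 is the smallest
radius–screening combination in the prescribed band and is kept as is.

## Regulation, titration, pKa machinery

η_g is reported as q_s/q_str (identical to q_s/eQ at full ionization).
Titration curves re-solve per pH with warm starts; pI is the linear
interpolation of the zero crossing (default grid step 0.25). ε_p inference
root-finds q_s(ε_p) = q_measured by bisection on [4, 78.5], where q_s is
monotone for single-sign group sets.

The core–shell model buries one titratable residue in a concentric core
(r_c = 0.6 nm, ε_c) inside a shell (outer radius 2.2 nm, ε_s) that carries
the molecule's background charge as a fixed uniform density (a composition
may instead be supplied and is titrated ideally per pH). The apparent pKa
is the pH at which the integrated core charge is half its full value. The
core group's charge is smeared over the core volume and kept in the Poisson
source, so it retains a small mean-field self-interaction (~+0.26 pKa units
in a bulk-like control); this term is what reproduces the observed upward
pKa shift (~+0.1) when r_c shrinks from 0.6 to 0.5 nm, so it is retained
deliberately rather than subtracted. The synthetic positive shell charge
(+8 e) used in tests stands in for a basic-protein background whose exact
composition is not part of the package's inputs; with ε_s = 40 and
ε_c ∈ [10, 25] the predicted glutamate pKa spans ≈ 4.9–8.0, and a Born
attenuation p = 0.25 moderates the downward shift of a buried lysine.

## What the benchmarks do and do not show

The fixture set is fully synthetic (uniformly charged spheres/cylinders and
sequence-derived inventories); passing tests demonstrate the mean-field
model's internal consistency (electroneutrality < 1%, Debye–Hückel limits
< 2%, Gauss-law vs density integrals < 1%, protocol insensitivities) and
agreement with published continuum benchmarks — not the accuracy of
mean-field PB itself for real molecules. Ion–ion correlations, ion size,
dielectric anisotropy and saturation, specific binding, conformational
flexibility and charge-fluctuation forces are all outside the model; for
compact proteins ε_p is an effective parameter absorbing those effects and
should be calibrated against a measured charge or isoelectric point.
Multivalent ions, activity corrections and temperature-dependent
dielectrics are out of scope.
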