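# Methods

## Model

`efgmep` solves the monodomain description of myocardial electrical
propagation: a single reaction-diffusion PDE for the transmembrane potential
v_m obtained from the bidomain model when intra- and extracellular
conductivities are proportional,

    ∇·(D ∇v_m) = A_m (C_m ∂v_m/∂t + I_ion) − I_s,

with the zero-flux natural boundary condition (D ∇v_m)·n = 0 of an isolated
heart. D is the local conductivity tensor: diagonal
diag(σ_f, σ_cf, σ_cf) in the fiber frame (fast along the myocyte direction,
slower across), rotated into the global frame by the fiber orientation. The
tissue is treated as a continuum; fiber discontinuities are not cut out of
influence domains.

Two membrane models are packaged:

* **Cubic polynomial ionic current** I_ion = g·v(1−v/v_th)(1−v/v_p), with
  potentials as deviations from rest (defaults: rest −85 mV, threshold
  deviation 10 mV, plateau deviation 100 mV, g = 0.004 mS/mm²,
  C_m = 0.01 µF/mm², A_m = 200 mm⁻¹). After nondimensionalization the 1D
  cable becomes the bistable (Nagumo) equation, whose unique traveling front
  has the closed-form speed γ = √(gσ/(A_m C_m²))·S/√(S+1), S = v_p/(2v_th)−1
  (0.566 mm/ms at σ = 0.5 mS/mm). The printed rendering of this formula in
  our source material was garbled; the implemented form was verified both
  algebraically (it equals the classical Nagumo front speed
  √(gσ/(2a·A_m·C_m²))(1−2a) with a = v_th/v_p) and against an independent
  fine-grid finite-difference cable simulation (within 2%).
* **Modified FitzHugh–Nagumo**: dimensionless excitation v ∈ [0,1] and
  recovery current I, f = c1·v(v−a)(1−v) − c2·v·I, dI/dt = b(v − d·I), time
  in ms, with defaults a = 0.13, b = 0.013, c1 = 0.26, c2 = 0.1, d = 1,
  diffusivities σ_f = 4, σ_cf = 1 mm²/ms.

## Spatial discretization (element-free Galerkin)

The geometry is a cloud of unstructured nodes; fields are approximated by
moving-least-squares (MLS) shape functions. Around an evaluation point the
nodes whose influence domain (radius d_mI = d_max·c_I, with c_I the
nearest-neighbor spacing of node I) covers the point contribute through a
compactly supported radial weight (cubic or quartic spline of
r = ‖x−x_I‖/d_mI). Minimizing the weighted residual of a monomial fit
(linear or full quadratic basis) gives φ = p(x)ᵀA⁻¹B with A = PᵀWP, B = PᵀW;
derivatives use (A⁻¹)_,k = −A⁻¹A_,kA⁻¹. The shape functions reproduce every
polynomial in the basis exactly (partition of unity in particular) but are
**not** interpolatory: φ_I(x_J) ≠ δ_IJ even at nodes (at the center of three
equispaced 1D nodes the cubic-weight values are (1/6, 2/3, 1/6)).

Numerical choices:

* the basis is evaluated in coordinates shifted to the evaluation point and
  scaled by the mean influence radius — a linear reparametrization that
  leaves φ unchanged and keeps the moment matrix well conditioned;
* the weighted least-squares system is solved through a QR factorization of
  √W·P rather than the normal equations, halving the effective condition
  number exponent; weights are clipped at zero against −1e−16 roundoff at
  the support edge;
* if a point is covered by fewer nodes than basis monomials (or than an
  optional `min_neighbors` floor), the search radius grows by factors of 1.2
  (at most 8 times) before a singular-moment-matrix error is raised;
* evaluation is batched: points are grouped by neighbor count and processed
  with stacked linear algebra; degenerate groups fall back to the scalar
  path.

Galerkin assembly integrates M_ij = ∫φ_iφ_j and K_ij = ∫∇φ_iᵀD∇φ_j on a
regular background mesh of equal axis-aligned cells covering the domain
bounding box, with tensor-product Gauss–Legendre points (1–4 per axis) per
cell. Quadrature points outside the domain are skipped with no weight
renormalization; on regular grids the mesh coincides with the node lattice.
The diffusion tensor at a quadrature point comes from MLS-interpolated nodal
fiber vectors, renormalized (with a nearest-node fallback when opposing
fibers cancel), using the identity D = σ_cf·I + (σ_f−σ_cf)·f·fᵀ, which
equals the rotated fiber-frame tensor for any unit fiber.

Because the shape functions are rational, the weak-form integrands are not
polynomials and Gauss quadrature is not exact: entries carry an O(1e−5)
integration residue at 4 points/cell near boundaries. This is intrinsic to
the method (and exactly why background-mesh density matters); the refinement
study below quantifies it.

## Time integration

The semi-discrete system A_m C_m dv/dt + M⁻¹K v = −A_m I_ion (consistent
mass by default) is advanced by:

* **forward Euler** with a spectral stability guard (power-iteration
  estimate of λ_max(M⁻¹K), dt capped at 1.8/λ_max). For the *linear* heat
  runs the Euler result (I − dt·M⁻¹K)ᴺ v₀ is evaluated by Lanczos iteration
  in the M-inner product with full reorthogonalization, converged to a 1e−12
  relative increment — identical to direct stepping to roundoff (verified:
  max difference ~1e−14) at a small fraction of the cost;
* **adaptive classical RK4** with step-doubling error control
  (Richardson estimate against atol + rtol·|y|, defaults rtol 1e−5,
  atol 1e−7, local extrapolation), cubic-Hermite interpolation for requested
  snapshot times, deterministic for fixed inputs.

M is factorized once: banded Cholesky when the node ordering gives a
moderate bandwidth (lattice orderings), sparse LU otherwise; a row-sum
lumped mass is available as a configuration switch for large irregular runs
(see the ventricle study).

Activation time at a node is the time of maximum upstroke velocity: a
centered finite difference of the recorded trace, refined by parabolic
interpolation of the discrete peak, with the search gated to the node's
rising phase (5–95% of its excursion) so the purely diffusive dv/dt spike
that a discontinuous stimulus induces in neighboring nodes at t ≈ 0 is not
mistaken for the upstroke. Nodes never exceeding a fallback threshold (half
the excitation amplitude) are flagged not-activated. Conduction velocity is
the centered difference of position versus activation time along the
propagation axis, with nodes within 10% of either end of the span excluded
*before* differencing; plane-wave speed over very coarse grids uses instead
the inverse slope of plane-averaged activation time vs coordinate over the
middle 60% of the span (excluding the stimulated face).

## Verification studies and their study conditions

**2D heat conduction.** On the centered square [−10,10]² mm the nodal field
is initialized from the radial fundamental solution
C = C₀/(4πσt)·exp(−(x²+y²)/(4σt)) at t = 1 (σ = 1 by default) and advanced
to t = 2 with 10⁵ forward-Euler steps (the step count is raised above this
floor if the stability cap demands it, as happens for d_max = 4 where the
consistent mass becomes nearly singular and λ_max reaches ~4e5/ms); the
figure of merit is the nodal RMS error against the kernel at t = 2. Node
lattices use spacings h ∈ {1, 0.5, 0.25} with the background mesh coincident
with the lattice and 4×4 Gauss points. The baseline is a bilinear Lagrange
FEM assembled on the identical lattice and quadrature. Measured behavior:
both FEM and d_max = 1.1 meshfree runs converge at second order with
parallel log-log curves (RMS ratio ≈ 1.26); d_max ∈ {2, 3} runs are two
orders of magnitude more accurate at every h; d_max = 4 degrades sharply on
coarse grids (2.3e−5 vs 4.8e−7 at h = 1 for d_max = 2). The
lower-order-quadrature-on-finer-mesh preference (2×2 points on a 2×-refined
mesh beating 4×4 on the coarse mesh at fixed h) is asserted at d_max = 1.5,
where integration error is the limiting term; at d_max = 1.1 the MLS
approximation error dominates and the comparison is insensitive.

**1D cable velocity.** A 20 mm fiber at spacing h, stimulated by setting the
first 5% of nodes to the plateau deviation, integrated by forward Euler with
dt = min(2e−3 ms, h²/(8D)) (the consistent-mass 1D operator has spectral
radius ≈ 12D/h²). Node-wise velocities are compared against the closed-form
γ with 10% end-trimming. An important property of this protocol, confirmed
with a mesh-independent fine-grid reference (h = 0.01 mm): the front needs
≈ 4 mm to reach its terminal speed (0.527 mm/ms at x = 2 mm vs 0.5657
asymptotically at σ = 0.5), so the node-wise RMS of any sufficiently fine
method is floored at ≈ 4.4e−3 mm/ms (σ = 0.5) / 1.0e−3 (σ = 0.25) by this
physical formation zone rather than by discretization. Coarse meshfree runs
(h = 0.8, d_max = 2) do not resolve the formation transient and lock
immediately onto steady propagation, which is why they reach a *lower*
node-wise RMS (≈ 7e−4 at σ = 0.5) than fine-grid FEM/FDM at h = 0.05 — the
efficiency result of interest (16× coarser nodes at equal or better error).

**3D cube plane waves.** FitzHugh–Nagumo in a 60 mm cube, one face layer
(nodes within one characteristic spacing of the face) initialized at
v = 0.5 — a layer of finite thickness, because a zero-thickness plane is a
subcritical source when the fast-diffusivity axis points into the domain.
Speed-vs-node-count curves for 2³ and 3³ Gauss points per cell (grids 5³ to
12³, background cells = lattice cells, d_max = 2, cubic weight) stabilize by
the 10³ grid at ≈ 0.21 mm/ms; the stabilization point is the smallest grid
whose speed changes by < 5% on the next refinement *and* keeps doing so for
every later refinement in the sweep (the extra clause guards against
coincidental agreement between two coarse grids). A 1106-node blue-noise
cloud reproduces the regular 10³ activation map with mean |Δt| ≈ 4% of the
activation-time span after nearest-neighbor pairing. With uniform fibers
(σ_f : σ_cf = 4 : 1) the along/across speed ratio is √4 = 2 within a few
percent.

**Synthetic left ventricle.** A stand-in geometry: a truncated prolate
ellipsoid shell (epicardial semi-axes 30/30/45 mm, endocardial 20/20/37 mm,
truncated 10 mm above center), filled with 3164 blue-noise nodes, with a
rule-based fiber field — helix angle interpolated linearly from −60° on the
endocardium to +60° on the epicardium in the local
circumferential–longitudinal plane. Stimulation mimics Purkinje exit sites:
6 endocardial patches (inner-wall nodes within 8 mm of seeds at evenly
spaced azimuths), fully depolarized and clamped for 20 ms. This protocol is
a nucleation necessity of this excitable medium on this geometry: point
kicks of a few nodes, and even large half-amplitude patches, are below the
critical nucleus (verified by simulation — they decay) because the FHN
reaction grows slowly (∼0.02/ms at v = 0.5) relative to diffusive dilution.
The run uses d_max = 2.5 with a 10-neighbor floor (the irregular thin shell
otherwise leaves quadrature points covered by as few as 4 nodes, with shape
values up to ±32 and a spectral radius ~670/ms) and the row-sum lumped mass
(λ_max drops to ≈ 5/ms), integrated by adaptive RK4. Acceptance is
qualitative, as for any synthetic stand-in: every node activates within the
window and the mean endocardial activation time precedes the epicardial one
(48.1 vs 54.3 ms at seed 3); an isotropic rerun shifts activation times by
well over 5 ms, confirming the fiber field matters.

## What the synthetic data does and does not show

All geometries (lattices, blue-noise clouds, the ellipsoid shell) are
generated by the package; no measured heart anatomy, fiber architecture or
activation data is used. Passing tests therefore demonstrate the numerical
properties of the discretization — consistency, convergence, anisotropy
handling, robustness on irregular clouds — not physiological fidelity: the
shell's activation sequence is an idealization (no Purkinje network
geometry, no transmural heterogeneity, one ionic time scale), and measured
human activation maps are not reproduced quantitatively.

## Known limitations

* Linear and quadratic bases only; no essential (Dirichlet) boundary
  machinery — every in-scope problem has pure zero-flux boundaries.
* Influence domains are never cut by material discontinuities (continuum
  assumption).
* Node-wise velocity RMS against the closed form depends strongly on the
  stimulus protocol through the front-formation zone (see the cable study);
  comparisons across publications require matching protocols.
* Explicit time integration only; the stiffness induced by oversized
  influence domains (d_max ≥ 4) or poorly covered quadrature points is
  guarded against but not removed (no implicit scheme).
* The empirical rule mapping nodes-per-cell to a quadrature order is
  exposed only as a logged advisory; every study pins its order explicitly.
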