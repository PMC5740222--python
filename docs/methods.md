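# Methods

## Model

The parenchyma is a saturated linearly elastic porous medium permeated by
four communicating fluid networks: arterial (a), arteriole/capillary (c),
CSF/ISF (e) and venous (v).  Quasi-static momentum balance (consolidation
regime, inertia neglected) couples the effective stress to all four pore
pressures through the Biot–Willis coefficients αᵢ; one continuity
equation per network balances storage (Sᵢ ∂pᵢ/∂t), poroelastic coupling
(αᵢ ∂∇·u/∂t), Darcy flow (−∇·(kᵢ/μᵢ)∇pᵢ) and inter-network transfer.
Transfer is linear in the pressure difference, ωᵢⱼ(pᵢ − pⱼ), on the
directed pair set a→c, c→v, c→e, e→v only; the arterial↔CSF path is
excluded *structurally* (requesting it is a model error, not a zero
coefficient), and the pairwise source/sink terms are antisymmetric by
construction, so the net transfer summed over networks vanishes
pointwise.

### Parameters

All internal units are SI.  Defaults (overridable via a flat YAML
mapping) are the published reference set for human parenchyma:
G = 216 Pa, λ = 505 Pa, α = (0.25, 0.25, 0.49, 0.01) for (a, c, e, v)
— summing to 1.00, satisfying ϕ ≤ Σα ≤ 1 with total porosity ϕ = 0.2 —
S = (2.9, 2.9, 3.9, 0.15)·10⁻⁴ m²N⁻¹, k = 10⁻¹⁰ m² for every network,
ω_ac = ω_cv = 1.5·10⁻¹⁹, ω_ce = 10⁻²⁰, ω_ev = 10⁻¹³ m²N⁻¹s⁻¹,
CSF production Q_p = 5.8·10⁻⁹ m³s⁻¹, venous back pressure p_bp = 650 Pa,
aqueduct drainage constant R = 8.5·10¹³ m⁻³, characteristic length
L = 70 mm and diameter d = 3 mm.  Viscosities are not part of the
reference table; the package defaults to standard literature values,
2.5·10⁻³ Pa·s for the blood networks and 1.0·10⁻³ Pa·s for CSF/ISF,
both overridable.

### Boundary conditions

Each condition is an isolated policy object so alternative readings can
be swapped without touching the assembly:

* **Cortical surface** — rigid skull: u = 0 (Dirichlet).  Arterial
  network: prescribed inward Darcy flux, the territory inflow Q(t)
  divided by the territory area (spatially uniform within a territory,
  so the integral of flux reproduces Q(t) exactly).  Capillary and
  CSF/ISF: impermeable (natural no-flux).  Venous: p_v = p_bp.
* **Ventricular wall** — no displacement constraint.  The ventricular
  CSF pressure p_vent is one extra scalar unknown: the ependymal CSF/ISF
  pressures are tied to it (master–slave), the wall carries the traction
  σ·n = −p_vent n, and the lumped reservoir balance closes the system:
  Q_p + Q_parenchyma→ventricle = Q_aqueduct + dV_vent/dt with
  Q_aqueduct = (p_vent − p_bp)/(μₑR).  The wall-motion volume term
  dV_vent/dt is included so the reservoir also feels the moving wall.
  Venous: p_v = p_bp; arterial and capillary: no-flux.

With zero inflow and zero production the exact solution is hydrostatic
equilibrium — all pressures at p_bp, u = 0 when Σα = 1 — and the
discrete system reproduces it to machine precision (see *Numerics*).

### Inflow waveforms and autoregulation

A parametric synthesizer stands in for subject-specific circulation
modelling.  Each cardiac cycle (default period 1 s) is a half-sine
systolic pulse occupying one third of the period, rising from the
diastolic baseline b to the calibrated peak, followed by exponential
diastolic decay from b toward 0.75·b with time constant T/3; b is solved
so the cycle mean equals `mean_to_peak`·peak (default 0.55, a typical
internal-carotid mean-to-peak ratio; feasible values are ≈(0.21, 1],
with 1 the degenerate constant-flow case).  Peaks default to the
published table of peak flow rates for one control and one MCI subject
in high/low activity states (e.g. control-high ICA_L 540.6 ml·min⁻¹).
The waveform peak is exact at a sample point by construction.

The autoregulation floor is a two-element feedback acting on flow: a
state x relaxing toward gain·max(floor − Q, 0) with time constant τ,
output max(Q + x, floor).  The error term is clipped at zero so the
controller is inert whenever flow exceeds the floor (output = input),
while the output never falls below the floor for any input; gain = 0
degenerates to pointwise clamping.

### Permeability tensor maps

One dimensionless SPD 3×3 tensor per tetrahedral element multiplies the
CSF/ISF base permeability; blood networks stay isotropic.  The
synthesizer produces eigenvalues (ratio, 1, 1) normalized to unit
determinant — keeping the geometric-mean permeability independent of the
anisotropy ratio, so ratio sweeps isolate directionality — with the
principal eigenvector set radially (mimicking predominantly radial
fibre orientation on shell geometry), by a fixed axis, or seeded
uniform-random.  Ratio 1 returns exact identity tensors, and a run with
an identity map is bitwise identical to a run with no map (both paths
build the same arrays).

## Discretization and numerics

Continuous P1 tetrahedra for displacement and all pressures, exact
element integrals (constant gradients), consistent mass matrices for
storage and transfer.  Time integration is monolithic backward Euler
(first order, verified by Richardson extrapolation); the system matrix
is constant over a run, so one sparse LU factorization (SuperLU) serves
every step.  Equal-order P1/P1 poroelasticity is stable here because the
storage coefficients keep the systems far from the undrained
incompressible limit; the benchmark setups were chosen in that regime
and pass the 1 % gates without pressure stabilization, so no quadratic
displacement option was built.

Implementation details that matter:

* **Dof ordering** — unknowns are interleaved node-by-node (u_x, u_y,
  u_z, p_a, p_c, p_e, p_v per node, lumped scalars last), which keeps
  LU fill local.  Dirichlet and tied dofs are eliminated through a
  sparse restriction x = T·y + g; tied groups (ependymal pressures, the
  rigid platen of the Mandel benchmark) sum their member equations into
  the master equation, which is exactly the flux/force balance.
* **Pressure reference shift** — pressures are solved as deviations
  from p_bp.  The arterial and capillary pressure *levels* are anchored
  only through ω-scaled entries ~10⁶–10¹⁵ times smaller than the Darcy
  terms; in absolute variables the constant 650 Pa component would be
  amplified by the condition number into O(10³ Pa) noise.  In deviation
  variables the equilibrium state is exactly zero and all solves work on
  the deviation scale.
* **Equilibration + iterative refinement** — the reduced matrix is
  symmetrically scaled by its diagonal before factorization, and each
  solve applies residual-based refinement (keeping the best iterate,
  since refinement can diverge when κ·ε ≈ 1).
* **Singularity detection** — after factorization the ratio
  min|U_ii|/max|U_ii| is checked; below 10⁻¹² the configuration is
  reported as numerically singular (e.g. a pure-Neumann pressure field
  with no transfer, storage or Dirichlet anchor) instead of returning
  garbage.
* **Conditioning limit of steady solves** — with the reference transfer
  coefficients (ω ≈ 10⁻¹⁹) the *steady* operator is numerically singular
  at working precision: the a/c levels are anchored by entries ~3·10¹⁵
  below the Darcy stiffness, so κ·ε ≈ 1 and no float64 direct solve can
  deliver flux-accurate steady solutions (transient solves are
  unaffected — storage anchors every level).  Steady-state studies
  (conservation checks, steady fixed-point tests) therefore use a
  "conductive" transfer set (ω = 10⁻¹⁰…10⁻¹², κ ≈ 10⁷).  The
  conservation identity being checked — inflow + production = venous
  outflow + aqueduct outflow, with boundary fluxes recovered exactly as
  Dirichlet-row residuals — is a property of the discretization and
  holds independent of the coefficient magnitudes; it closes to ~10⁻⁹
  relative.

## Verification

* **Terzaghi column** — 1-D consolidation under a suddenly applied
  drained-surface load.  Oracle: the classical Fourier series with
  c_v = (k/μ)·M·m_v/(m_v + α²M) (m_v = λ + 2G, M = 1/S) and undrained
  initial pressure αMq/(m_v + α²M); the series is itself cross-checked
  against an independent explicit finite-difference solve of the
  diffusion equation (agreement ~10⁻⁶ relative).  The FEM column
  (lateral rollers, traction-loaded drained top, analytic undrained
  initial state) matches the series to 0.28 % space–time relative L2 at
  the default refinement.
* **Mandel slab** — rigid frictionless platens (tied-dof platen with a
  total-force master equation), drained lateral edges, plane strain.
  Oracle: the series in the roots of tan a = (1−ν)/(ν_u−ν)·a with
  p₀ = B(1+ν_u)σ̄/3, validated against its own undrained closed form.
  The benchmark setup uses S = 5·10⁻⁸ Pa⁻¹, λ = 2 MPa, G = 3 MPa
  (ν = 0.20, ν_u = 0.44) so the Mandel–Cryer overshoot is pronounced
  (~6 %); FEM matches the series to 0.24 % and reproduces the
  non-monotone centre pressure.
* **Temporal order** — Richardson study on the column at fixed mesh:
  error ratios ≈ 2.1–2.3 under dt halving, consistent with first-order
  backward Euler.
* **Mesh independence** — the full four-network brain configuration
  (identical parameters, inflow, 0.25 s window) on a four-member shell
  family of 480 / 1 620 / 7 500 / 17 640 elements; volume-weighted
  domain means of |u|, the four pressures and the four Darcy speeds all
  show successive-refinement differences decreasing after the first
  refinement.  The family size is the package's choice of desk-scale
  problem sizes (a single 3-D LU at ~50 k dofs already costs minutes and
  gigabytes); the trend, not a specific element count, is the check.

## What the synthetic data does and does not show

The shell geometry, radial tensor maps and parametric waveforms emulate
the *structure* of the real problem — two labeled boundary surfaces,
four perfusion territories, anisotropic CSF/ISF transport, pulsatile
territory inflow with activity states — but not subject anatomy:
no sulci/gyri or ventricular horns, territory areas differ from real
cortical partitions, and waveform shape beyond the calibrated peak/mean
is generic.  Passing tests therefore demonstrate correctness of the
solver and its couplings, and qualitative behaviours (clearance
channelled along fibre directions, activity-dependent ICP/ABP ranges,
periventricular accumulation patterns); they do not reproduce
subject-specific magnitudes, which depend on imaging-derived meshes,
tensor maps and Holter-calibrated waveforms.

## Known limitations

* Quasi-static, linear kinematics; no subarachnoid space compartment
  (the rigid-skull condition sits directly on the cortex) and no
  cross-porosity storage coupling.
* Steady solves with the reference transfer coefficients are outside
  float64 reach (see above); transient studies are the intended use.
* P1 equal-order elements: configurations approaching the undrained
  incompressible limit (S → 0 at coarse dt) would need stabilization or
  a mixed element; the shipped benchmark regimes do not.
* Direct factorization bounds practical mesh sizes to ~10⁵ elements on
  a workstation; larger runs need an iterative solver.
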