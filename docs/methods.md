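# Methods

## Model

The lipid tubule is described by a scalar order parameter φ(r, z) on an
axisymmetric cylindrical domain, with φ → +1 in the lumen, φ → −1 outside,
and the membrane as the diffuse transition layer around the φ = 0 midplane.
The elastic free energy is a Ginzburg–Landau functional whose three terms
converge, as the interface-width parameter ε → 0, to the bending, Gaussian
and tension terms of the Canham–Helfrich Hamiltonian (prefactors in the
README). The regularized Gaussian term is the essential ingredient: it
keeps the energetics well defined across the change of topology at
fission, which a sharp-interface description cannot follow.

The coupling between ε and the physics is deliberate: the diffuse layer
spans ≈ 6ε and is matched to the bilayer thickness, 6ε = l_me = 5 nm, so
ε = 5/6 nm. This makes the model's "smallest resolvable structure" the
bilayer itself; sub-bilayer detail (leaflets, hemifission intermediates)
is outside the resolution of a single scalar field by construction.

### Dynamin forcing

The coat model needs only the helix's mesoscopic geometry: length H, pitch
h, dimers per turn N_d, and the tangential power-stroke force F_τ. Ratchet
strokes between dimers of adjacent rungs build a hoop tension along the
chain, which projects onto the membrane as an inward pressure with a 1/r
radial dependence, p = N_d F_τ/(h r), on the coat footprint.

Two shape functions close the model and are surrogates for structural
detail we do not model explicitly:

* **Axial envelope A(z).** Tension builds across the two extremal rungs
  and is constant over the inner ones, so A ramps (half-cosine) from zero
  at each coat end to 1 over one pitch, *inside* the footprint; the
  support is exactly H. For a two-rung coat (H = 2h) the profile is a
  single cosine bump. Placing the ramps outside the footprint instead
  (support H + 2h) systematically inflates the effective coat length and
  with it the critical energy, and is not used.
* **Radial cutoff C(r).** The helix cannot constrict below a structural
  curvature limit, taken as tubule radius R_cut = 3 nm; C is a tanh ramp
  of width 0.5 nm centered there. Critical energies change by < 1% when
  the width is doubled, consistent with the robustness expected of this
  choice.

The pressure lives on the Eulerian grid, independent of φ; it couples to
the membrane only through I[φ] = ∫ h(φ) p dV with h(φ) = ¾(φ − φ³/3),
whose normal derivative across the interface integrates to exactly 1 — the
diffuse equivalent of a surface-delta pressure. On fission the overlapping
coat is deactivated (depolymerization); no energy is deposited.

### Dynamics

φ relaxes by non-conserved (Allen–Cahn) gradient descent,
∂φ/∂t = −M_pf δF/δφ, the overdamped, maximum-dissipation-rate dynamics of
the membrane with mobility M_pf = 4.04 nm³/(s·k_BT); its sharp-interface
counterpart is M_sharp = 3ε M_pf/√8 = 3.57 nm⁴/(s·k_BT). There is no
thermal noise: trajectories are deterministic and the total free energy is
a Lyapunov function while the coat configuration is fixed.

## Numerics

* **Grid and differentiation.** Homogeneous cell-centered (r, z) lattice;
  z is periodic, r is handled by mirror extension across the axis (even
  for scalars, odd for radial vector components), making all derivatives
  FFT-spectral. The cell-centered grid never samples r = 0, so the 1/r
  metric terms are regular. The outer radial boundary carries an even
  (zero-normal-derivative) extension; fields must reach their bulk value
  before L_r, which run configurations check. Production spacing is
  dr = dz = 30/108 ≈ 0.28 nm ≈ ε/3.
* **Gaussian-energy variation.** δF_G/δφ is assembled analytically from
  the first variation of ψ_G, grouped into one divergence and one
  Laplacian so it costs two spectral passes; its correctness is certified
  by a directional-derivative (Gateaux) test against centered differences
  of the energy itself (relative agreement ~1e-6 at production spacing).
* **De-aliasing.** The 2/3-rule truncation is applied to every update.
  The quintic-order nonlinearities of ψ_G otherwise alias onto the highest
  retained modes and pump a slow sawtooth instability. Consequently the
  dynamics evolves in the truncated subspace; stationarity is measured on
  the projected gradient, and initial conditions are projected once.
* **Time stepping.** Each step solves the backward-Euler equation
  φ⁺ = φ − Δt M_pf δF/δφ(φ⁺) by a chord iteration preconditioned in
  spectral space with the constant-coefficient bound of the
  bending+tension Jacobian, S(k) = M_pf [c_b (2 + ε²k²)² + c_t (2 + ε²k²)].
  One iteration is the classical stabilized semi-implicit update; iterating
  to convergence removes that scheme's 1 + Δt S(k) retardation of slow
  interface motion, which at useful step sizes would slow constriction by
  orders of magnitude. A linear-extrapolation predictor from the previous
  step usually leaves a single correction sufficient (≈1.15 evaluations
  per step in production runs) and an effectively second-order remainder
  (observed gap ratios ≈ 4–7 under Δt halving). The inner tolerance is
  two-regime: during active evolution it is a fixed fraction (2%) of the
  step's own size, so the solver error stays proportional to the motion;
  when Δt sits at its ceiling (quiescent phases) the solve is driven to a
  tight absolute tolerance (1e-6), because a partially converged solve
  leaves correlated error that can feed a slow numerical limit cycle
  through the predictor. The Δt ceiling (default 0.25 s) is likewise a
  stability choice for near-equilibrium phases.
* **Adaptive step.** Δt is controlled so the per-step max |Δφ| stays near
  `dphi_target` (default 0.01, i.e. interface displacements of
  ~0.01·√2·ε ≈ 0.01 nm per step); steps that exceed 3× the target or whose
  inner iteration stalls are rejected and retried at Δt/2. At the default
  target, halving it changes the measured H = 20 nm fission time by 0.2%
  and the critical energy by 0.3%.
* **Equilibrium detection.** A run is declared at equilibrium when the
  de-aliased max |δF/δφ| falls below 3e-5 k_BT/nm³ — just above the floor
  left by the finite inner tolerance; tighter thresholds are configurable
  but require proportionally tighter inner tolerances.
* **Fission detection.** The tubule is severed when at least one z column
  is entirely φ < 0 (the φ > 0 phase is disconnected along the axis). A
  single scalar field cannot distinguish hemifission from full fission;
  the detected event is lumen disconnection.

## Observables

Necks are local minima of the midplane radius r(z) with topographic
prominence ≥ 0.5 nm (suppressing grid-scale ripples); R_n is the global
minimum, R_c the radius at the coat center, D the distance between the two
outermost necks. The critical state is the maximum-F_e state over the
pre-fission window of a trajectory that ends in fission (no fission, no
critical state), and its activation energy ΔF_e is referenced to the
unperturbed tubule. The energy split integrates the excess linear energy
density between the outermost necks (inner) and outside them (flanks);
with fewer than two necks the inner part is zero by convention.

The normalized lumenal conductance G_n(t) uses a series-resistor model
along the axis with conducting radius r_lum = max(0, r_mid − l_me/2 − λ_D),
λ_D = 1 nm (physiological screening); the exact Debye correction model
cancels to leading order in the normalized trace, which is the only
quantity reported.

## Parameter defaults

| parameter | default | units | meaning |
|---|---|---|---|
| k_b | 20 | k_BT | bending rigidity |
| k_G | −k_b | k_BT | Gaussian modulus |
| γ | 1.5e−4 | N/m | reservoir surface tension |
| l_me | 5 | nm | bilayer thickness (6ε) |
| M_pf | 4.04 | nm³/(s·k_BT) | phase-field mobility |
| h | 10 | nm | helix pitch |
| N_d | 13 | — | dimers per turn |
| F_τ | 2.5 | pN | power-stroke force |
| R_cut | 3 | nm | curvature cutoff radius |

These give R_in = 16.6 nm, γ̄ = γ + N_d F_τ/h, R_c ≈ 3.5 nm,
H*_l.e. = 2√2π R_in ≈ 147.5 nm.

## Study scales

The full-scale domain is 30 × 1400 nm (108 × 5040 cells). Tests and the
acceptance pipeline use a reduced 30 × 360 nm domain (108 × 1296) at the
same spacing: the elastic response decays over √2 R_in ≈ 23 nm, so a coat
centered in 360 nm keeps > 5 decay lengths of clearance and the critical
radii/energies are insensitive to the truncation. Single reduced-scale
fission runs take ~3–6 min on one CPU. The weak-forcing linear-response
comparison uses a smaller, higher-tension tubule (k_b = 16 k_BT,
γ = 5e−4 N/m, R_in ≈ 8.1 nm) where equilibration is faster.

## What the synthetic fixtures do and do not show

`tubefission.synthetic` builds contours, phase fields and trajectories
with prescribed radius profiles and energies. They validate the observable
definitions (neck counting, conductance monotonicity, critical-state
selection, energy-split bookkeeping) independently of the PDE dynamics.
They do not exercise the elastic model itself — that is what the
sharp-limit energy tests and the reduced-scale simulations are for — and
none of the fixtures emulates thermal fluctuations, lipid heterogeneity or
protein-level structure, which the continuum model does not contain.

## Known limitations

* Hemifission and leaky intermediates are not resolved (single field).
* The pressure model assumes a preassembled, GTP-saturated coat; no
  polymerization dynamics, helix elasticity or shear transmission.
* Near the neck-splitting threshold H* the dynamics slows critically
  (the constricted central region is a quasi-equilibrium of the modified
  tension), so runs just above H* take substantially longer to fission
  than short-coat runs.
* Conductance is reported only as a normalized ratio; absolute siemens
  values would need the lumen conductivity model.
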