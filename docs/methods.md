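# Methods

## Model

A single epithelial cell is described by three coupled fields on a periodic
square domain: a phase field φ (1 inside, −1 outside, diffuse interface of
thickness ∝ ε), a polar orientation field P for the mean microtubule
direction, and a Stokes velocity/pressure pair (u, p) with unit fluid
density inside and outside the cell. The system evolves by gradient descent
of the free energy E = E_kin + E_S + E_P with advection of φ and P by the
flow.

**Membrane energy.** E_S is the Cahn–Hilliard surface energy
(1/Ca)∫(ε/2)|∇φ|² + W(φ)/ε dx with the quartic well W(φ) = ¼(φ²−1)²
(minima at the two bulk phases; any well with that property would do — the
quartic is the standard choice). Its sharp-interface limit is a line
tension σ = (2√2/3)/Ca. Bending resistance uses the diffuse Willmore form
(1/Be)∫(1/2ε)(ε∇²φ − W′(φ)/ε)² dx, the standard phase-field approximation
of the Helfrich energy with zero spontaneous curvature; for a circle of
radius r ≫ ε it converges to (2√2/3)·π/(Be·r), i.e. the Willmore energy of
the circle times the same profile constant.

**Microtubule energy.** E_P = ∫(κ_P/2)|∇P|² + (1/4δ_P)(|P|² − φ̃²)² dx with
φ̃ = (φ+1)/2. The penalty weakly enforces |P| = 1 inside the cell and P = 0
outside; the target |P| = φ̃ (rather than √φ̃) makes the orientation field
decay across the interface at least as fast as the interior indicator,
which is what "vanishes outside the cell" should mean operationally, and
makes the initial condition P = (1,0)·φ̃ an exact minimizer of the penalty.

**Forces.** The active stress is σ_a = (1/Fa)φ̃ P⊗P with Fa < 0; its
divergence pushes the interface outward along ±P (protrusion), with
strength 1/|Fa|. The passive coupling force on the fluid is the
thermodynamically conjugate one, f = μ∇φ + (∇P)ᵀ(δE_P/δP) with
μ = δ(E_S+E_P)/δφ: with this sign the power the force injects into the
Stokes flow equals the advective energy loss of the fields, so with the
active stress switched off the discrete total energy is non-increasing
(verified in the tests step by step). Ericksen/corotational stresses and
flow alignment of P are deliberately omitted; the dynamics of P are pure
advection plus gradient-descent relaxation.

## Discretization

Space: uniform periodic grid, all derivatives spectral (real FFTs);
integrals by the periodic trapezoid rule, which is spectrally accurate.
Nyquist modes of the first-derivative symbols are zeroed so the discrete
gradient is exactly skew-adjoint; as a result the implemented variational
derivatives are the exact discrete gradients of the implemented energies
(directional-derivative tests agree to ~1e−9 relative).

Time: first-order IMEX. The stiff linear parts — the ∇⁴/∇⁶ terms of the
conserved φ flow and the κ_P∇² distortion of P — are implicit in Fourier
space, with an Eyre-type k² stabilization (coefficient 2/(Ca·ε)) for the
explicitly treated −W′ antidiffusion. The stiff norm penalty of P is
applied as an exact pointwise logistic substep for m = |P|² (unconditionally
stable, direction-preserving), which is what allows δ_P = 0.01 at dt = 0.01.
Advective products are dealiased by the 2/3 rule, and the k = 0 mode of the
φ advection term is zeroed (∫u·∇φ dx = 0 for divergence-free u), so mass is
conserved to round-off. The Stokes problem is solved exactly in Fourier
space by Leray projection with zero-mean gauge for u and p; the mean force
is removed (solvability on the torus).

Per step: (1) variational derivatives of the current fields, (2) body force
and Stokes solve, (3) transport/relaxation updates of φ and P with the
fresh velocity. A guard raises a step-failure error naming the offending
field if values become non-finite or |φ| exceeds 1.05. The solver contains
no randomness; identical inputs give bit-identical trajectories.

Note on the energy audit: in Stokes flow the velocity is slaved to the
fields, so the kinetic energy of the prescribed rest initial state (u = 0)
jumps at the first step. The dissipation audit therefore starts from the
first slaved state; from there e_total decreases monotonically.

## Parameters and geometry

The physical controls are Ca, Fa (varied per regime: balanced −1/0.1,
reduced protrusion −10/0.1, reduced tension −1/1) and Be (fixed at 1 across
regimes). The remaining constants are closure choices of this
implementation, fixed once:

| parameter | default | role |
|---|---|---|
| ε | 2h (1.875 at 128²) | interface thickness; resolution requires ε ≥ 2h |
| η | 1 | fluid viscosity; sets the overall relaxation timescale |
| κ_P | 0.01 | orientation distortion modulus |
| δ_P | 0.01 | norm-penalty scale (smaller = harder |P| constraint) |
| γ_φ | 1 | Cahn–Hilliard mobility (interface regularization) |
| γ_P | 1 | orientation relaxation rate |
| dt | 0.01 | IMEX step; halving dt changes t=5 Feret by < 0.1% |

Geometry: initial ellipse with semi-axes a = 15, b = 10 (aspect 1.5),
domain side 4·(2a) = 120, grid 128², output at t = 0…5. The absolute cell
size is the one genuinely free choice: the model has an intrinsic length
scale set by the tension/activity balance, σ·(κ_tip − κ_side) ≈ 1/|Fa|,
where κ_tip = a/b² and κ_side = b/a² are the boundary curvatures at the
ends of the axes. With σ = 9.43 (Ca = 0.1) and |Fa| = 1 this balance gives
b ≈ 10 at aspect 1.5, so the chosen ellipse starts near mechanical
equilibrium for the balanced regime — which is precisely what that regime
is meant to depict. The closure constants above were fixed from this
force-balance estimate plus short solver runs and then frozen; all three
regimes and their strict ordering follow without per-regime tuning.
Refining 96² → 192² at fixed ε changes the balanced final Feret diameter
by < 0.1%.

## Quantification

* **Contours**: marching squares with linear interpolation on φ; the
  largest closed component is used and the component count reported. No
  polygon smoothing — the small positive perimeter bias of marching-squares
  polygons is visible as circularity slightly below the analytic value.
* **Shape descriptors**: shoelace area, edge-sum perimeter, circularity
  4πA/p² (stored exactly as that expression), Feret major = maximum
  caliper = largest hull-vertex distance, Feret minor = minimum caliper
  width over hull-edge normals, elongation index = their ratio. Angles are
  axial, folded to (−90°, 90°], 0° = P/D (x) axis.
* **Orientation from images**: Gaussian-windowed structure tensor
  (reflective boundary handling); feature orientation is perpendicular to
  the dominant gradient eigenvector, θ = ½·atan2(2J_xy, J_xx−J_yy) + 90°;
  coherence (λ₁−λ₂)/(λ₁+λ₂) masks unreliable pixels. The per-pixel default
  threshold is 0.2; for pooling over dense filament textures a stricter 0.5
  is used (crossing points and segment ends have low coherence and would
  otherwise bias the pooled histogram). Pooled histograms are weighted by
  coherence (for images) or |P| (for fields); this weighting is a choice,
  stated here because the measurement convention does not fix it.
* **Angular binning**: three categories 0–30°, 30–60°, 60–90° on the
  absolute angle with the P/D axis; the signed scheme pairs ±bins and is
  numerically identical after folding. Bins are left-closed, right-open,
  last bin closed at 90°.
* **Recoil velocity**: (d(0.2 s) − d(0))/0.2 s from vertex-separation
  tracks sampled every 200 ms over 2 s.
* **Junction intensities**: background subtraction, then division by the
  mean background-subtracted control-junction intensity.

## Synthetic data

The generators exist so every measurement has a ground truth. Filament
images draw axial angles from a von Mises distribution on the doubled angle
(the standard axial model; defaults: mean 0°, κ = 8, 500 segments of
60 px on a 512² image, 1 px blur, additive noise sd 0.05 — a dense but
resolvable texture), render anti-aliased segments, and return the true
per-segment angles. Ablation tracks are d(t) = d0 + A(1 − e^{−t/τ}) with
optional Gaussian noise, returning the closed-form noiseless initial recoil.
All fixtures are bit-reproducible from their spec and seed; the simulator
itself is seed-free.

What these fixtures do not emulate: real micrograph point-spread functions,
uneven illumination, filament curvature and bundling, out-of-plane signal,
or manual tracking error in ablation data. Passing the recovery tests shows
the estimators are correct on well-posed inputs, not that they are robust
to every imaging artifact.

## Known limitations

* 2D, single cell, no cell–cell mechanics, no inertia, no 3D apical/basal
  structure.
* The E_P closure, double-well, bending discretization and the closure
  constants are this package's choices; other implementations of the same
  continuum model (e.g. finite-element ones) may differ coefficient for
  coefficient, so agreement is at the level of regimes and orderings, not
  decimal places.
* First-order time accuracy; the regime comparisons are dt-converged at the
  default step, but sharp-interface limits (ε → 0) are not pursued.
* The balanced regime holds its length to a few percent over t ≤ 5; it is
  near, not exactly at, a true steady state (slow residual Cahn–Hilliard
  relaxation persists).
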