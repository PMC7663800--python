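# Methods

## Problem

Synthetic vascular grafts fail in part because their pressure–diameter
response (compliance) mismatches the native vessel. The package models a
candidate graft material — a polyurethane (PU) blend characterised by
uniaxial tension — in two stages:

1. **Constitutive fit.** A three-parameter Mooney–Rivlin hyperelastic model
   is fitted to a uniaxial true stress–stretch curve, yielding the
   coefficient triple (C10, C01, C11), goodness-of-fit (RMSE, Lin's CCC),
   and the rubber-elasticity crosslink density v = |C10|/(RT).
2. **Graft simulation.** A cylindrical tube of the fitted material is placed
   under a sinusoidal physiological pressure; thick-wall hoop stress is
   mapped through the inverse of the constitutive law to a stretch, radius
   and compliance history, swept over frequency and geometry grids.

## Constitutive model

For principal stretches (λ₁, λ₂, λ₃) the invariants are
I₁ = λ₁²+λ₂²+λ₃², I₂ = λ₁⁻²+λ₂⁻²+λ₃⁻², I₃ = λ₁²λ₂²λ₃². Incompressibility
(I₃ = 1) under uniaxial extension gives λ₁ = λ, λ₂ = λ₃ = λ^(−1/2). The
energy density keeps the first-order and cross terms,

    W = C10 (I₁−3) + C01 (I₂−3) + C11 (I₁−3)(I₂−3)   [MPa],

and eliminating the hydrostatic pressure with σ₂ = σ₃ = 0 yields the
uniaxial Cauchy stress

    σ₁(λ) = 2 C10 (λ²−1/λ) + 2 C01 (λ−1/λ²)
          + 6 C11 (λ³−λ²−λ+1/λ+1/λ²−1/λ³).

Two independent identities are enforced by the test-suite: σ₁ = λ dW/dλ on
the uniaxial path (central differences), and
σ₁ = 2(λ²−1/λ)(∂W/∂I₁ + λ⁻¹ ∂W/∂I₂).

**Engineering → true measures.** λ = 1 + ε_eng and σ_true = λ σ_eng, the
standard incompressible-uniaxial relation (the current cross-section shrinks
by 1/λ). The alternative reading σ_true = σ_eng/λ would violate volume
conservation and is not offered.

**Fitting.** σ₁ is *linear* in (C10, C01, C11), so the least-squares problem
is solved exactly by SVD on the three basis functions; no initial guess,
no convergence ambiguity, and the solution is the global optimum of the same
objective a generic nonlinear regression would minimise. A
Levenberg–Marquardt path (`method="nls"`) exists purely as a cross-check and
agrees with the linear solution to below 1e−8. A rank-3 design is required
(≥ 3 distinct stretches above 1); Drucker-type sign constraints are *not*
imposed — fitted elastomer triples routinely carry negative coefficients
while remaining monotone over the working range — and the graft simulator
instead verifies monotonicity of σ₁(λ) where it matters. The reported
`initial_slope` 6(C10+C01) is the analytic dσ₁/dλ at λ = 1 (the C11 bracket
is flat there).

**Goodness of fit.** RMSE = √(mean squared residual) in MPa, and Lin's
concordance correlation coefficient
CCC = 2s_xy / (s_x² + s_y² + (x̄−ȳ)²) with population (1/n) moments, per
Lin's original estimator. CCC measures agreement with the identity line and
satisfies |CCC| ≤ |Pearson r|.

**Crosslink density.** v = |C10|/(RT) with C10 in Pa and
R = 8314 J kmol⁻¹ K⁻¹, giving v in kmol/m³ at T = 310.15 K (37 °C). The
magnitude is taken because fitted C10 may be negative while the published
densities for the same materials are positive and numerically equal to
|C10|/(RT); for one reference composition (47.5–47.5–5) the published value
(0.32) differs from |−0.812|/(R·310.15) = 0.31 in the last printed digit,
most plausibly rounding of an unprinted C10 digit on the publication side —
that row is documented rather than asserted.

## Graft simulation

* **Waveform.** P(t) = Pm(1 + ε sin(2πft)), ε = Ps/Pm, with
  Pm = ⅓P_max + ⅔P_min. Defaults: P_max/P_min = 180/40 mmHg → Pm = 86.67
  mmHg, Ps = 10 mmHg, f = 1 Hz. The frequency is an ordinary frequency in
  Hz; the 2π lives in the sinusoid argument so one pressure cycle is one
  cardiac cycle.
* **Hoop stress.** Thick-wall estimate
  σ_θθ = P·(r0²/(r0+h)²)·(1 + (r0+h)²/r0²) = P·(1 + r0²/(r0+h)²), converted
  with 1 mmHg = 1.33322×10⁻⁴ MPa. It is homogeneous of degree zero in
  (r0, h): geometry enters only through h/r0, which is the exact mechanism
  behind the finding that uniform radius/thickness scaling does not change
  compliance.
* **Stretch inversion.** σ₁(λ) = σ_θθ is solved by bracketed root finding
  (Brent, xtol 1e−14) on [1, 3]; monotonicity of σ₁ on the bracket is
  verified by sampling (512 points) first, and a target of exactly zero
  returns λ = 1. Physiological hoop stresses here are ~0.02–0.04 MPa against
  MPa-scale moduli, so stretches stay below 1.05.
* **Radius and compliance.** r(t) = r0·λ(t); compliance is the forward
  difference (r_{i+1}−r_i)/(r_i(P_{i+1}−P_i)) in 1/mmHg. At pressure turning
  points the difference quotient is 0/0; samples with |ΔP| < 1e−6 mmHg
  become explicit NaN gaps, never zeros or infinities, and summary
  statistics skip them.
* **Time grid.** 256 samples per cycle (default), 3 cycles, with the first
  cycle dropped from summaries as a cheap guard (an elastic model has no
  transient, so nothing is lost). The sinusoid phase is evaluated modulo one
  cycle, so samples at the same phase of different cycles are bit-identical
  and the compliance series is *exactly* periodic — large-argument sine
  round-off never masquerades as rate dependence.
* **Sweeps.** Defaults f ∈ {1, 1.5, 2} Hz, r0 ∈ {1.5, 2, 3} mm,
  h ∈ {0.3, 0.4, 0.5} mm (h spans the cast-film specimen thickness range);
  per-cell failures are collected, not raised, so one unstable cell cannot
  void a sweep. Summaries report min/max/mean compliance per cell, also
  ×10⁴ (the conventional reporting scale).

## Synthetic tensile data

No tensile records are deposited with the reference characterisation, so the
generator produces curves with the statistical structure the analysis
assumes, with the published hydrated-state coefficient triples as ground
truth:

* forward evaluation of σ₁ on a uniform stretch grid [1, λ_max], reported on
  the engineering scale σ_eng = σ₁/λ, first sample pinned to (0, 0);
* additive Gaussian noise (default sd 0.02 MPa) on *engineering* stress —
  the instrument measures force over original area — clipped at zero; the
  magnitude is a package choice (no instrument noise figure is published)
  and is roughly 1% of a typical ultimate strength;
* per-replicate multiplicative lognormal jitter on each coefficient (unit
  mean, default CV 5%, five replicates) — multiplicative so coefficient
  signs, and hence the model's character, are stable across replicates;
* hydration softening as a uniform coefficient scale factor in (0, 1] — the
  minimal mechanism for a plasticiser that softens without reshaping the
  response; real hydrated curves also terminate earlier, which callers model
  by lowering λ_max.

What the generator does **not** emulate: stress-induced crystallisation
upturn beyond the Mooney–Rivlin representation, toe-region artefacts, grip
slippage, rate dependence, or hysteresis. Passing tests therefore
demonstrate correctness of the estimation and simulation machinery under the
model's own assumptions, not robustness to every artefact of real DMA
exports.

Replicate averaging interpolates each curve linearly onto a uniform stretch
grid (default 200 points) on [1, min over replicates of max stretch] — the
shortest replicate truncates the grid — and reports the pointwise mean and
sample sd (ddof = 1; zero for a single curve).

## Numerical and design choices

* Units contract: MPa internally; mmHg accepted/reported at the pressure
  boundary; strain as fraction with an opt-in percent flag.
* Result tables are written at `%.17g`, so write→read round-trips are exact
  to the last bit (readers use round-trip float parsing).
* Fitting uses true stress vs stretch; curves are validated (strictly
  increasing strain from ≥ 0, non-negative stress, ≥ 3 points) at
  construction, and readers never silently reorder rows.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`, with a fixed per-material substream offset in
  multi-material runs; identical config + seed reproduces output files
  byte-for-byte.
* Problem sizes in the shipped analysis (200-point curves, 5 replicates,
  500-draw Monte-Carlo recovery, 27-cell sweeps at 256 samples/cycle) were
  chosen so the whole pipeline completes in seconds while leaving
  Monte-Carlo standard errors well inside the asserted tolerances.

## Limitations

* The wall model is a single-layer, isotropic, purely elastic tube with a
  closed-form hoop-stress estimate; no anisotropy, no bilayer structure, no
  axial pre-stretch, no viscoelasticity, no fluid–structure interaction.
  Creep/recovery and strain-sweep behaviour are outside the constitutive
  model entirely (the package's dynamic-moduli helper only converts
  amplitude/phase measurements, it does not predict them).
* Coefficients derive from uniaxial data only; planar/biaxial states are
  extrapolation.
* Compliance is reported both pointwise (forward difference) and as
  per-cycle min/max/mean summaries; published figure-read compliance
  magnitudes are not reproduction targets because the underlying
  experimental curves are unavailable.
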