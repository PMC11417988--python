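# Methods

## The model

`gtafit` fits time-resolved spectral surfaces `TRS(t, ω)` — femtosecond
stimulated Raman (FSRS) gain/loss surfaces and visible transient-absorption
(TA) surfaces, in mOD on a delay axis in ps — with a superposition of three
terms per detection pixel ω:

```
TRS(t, ω) = Σ_l  c_l(t; θ) · SADS_l(ω)                         (populations)
          + Σ_n [A_c,n(ω) B_c,n(t, ω; θ) + A_s,n(ω) B_s,n(t, ω; θ)]   (CA)
          + IRFAS(ω) · irf(t, ω; θ)                             (scatter)
          + residual(t, ω)
```

**Populations.** A compartmental scheme (first-order channels between named
states, losses routed to an implicit ground-state sink) compiles to a
transfer matrix `K`; rates are declared in ns⁻¹ (the customary unit for
branched carotenoid schemes) and converted to ps⁻¹ internally, matching the
delay axis.  With a Gaussian instrument response of width σ centered at
μ(ω), the populations are linear combinations of the closed-form convolved
exponentials

```
E(k, t) = ½ exp(k²σ²/2 − k(t−μ)) erfc((kσ² − (t−μ)) / (σ√2))
```

over the eigenmodes of `K`.  `E` is evaluated through the *scaled*
complementary error function (the Faddeeva function for complex `k`), with a
branch split at Re(z) < 0, so it never overflows — also for decay rates as
fast as 1/71 fs or strongly off-resonant oscillation kernels.

**Dispersion.** The IRF center varies with detection position (chirp):
μ(ω) = μ₀ + Σ_p d_p·((ω − ω_c)/100)^p, default order 2.  The width σ is
given as fwhm = 2√(2 ln 2)·σ in user-facing code, and may be *linked* across
experiments so that several surfaces share one free width.

**Coherent artifact.** Prezero resonance signals (perturbed free induction
decay of the probe under the picosecond Raman pump, halted by the actinic
pump) are damped oscillations at the difference frequency ω − ω_n for each
ground-state Raman resonance ω_n.  The default kernel direction is
*backward*: `cos(Δω t′ − φ(ω)) exp(γ t′)` for t′ = t − μ(ω) < 0 and zero
after the pump — a literally forward-damped oscillation cannot produce
prezero signal, so backward is the physically coherent reading; a forward
(post-zero) variant is available as an option.  Each oscillation contributes
two conditionally linear columns per pixel (the IRF-convolved cosine-like
and sine-like bases, the real and imaginary parts of the convolved reversed
complex exponential with κ = γ + iΔω, Δω = 2πc(ω − ω_n), c = 0.0299792458
cm/ps); the damped-oscillation-associated spectrum and phase follow
post-hoc as `DOAS = √(A_c² + A_s²)` and `φ = atan2(A_s, A_c)`.  Keeping the
phase out of the nonlinear parameter vector preserves the exact
linear/nonlinear separation.

**Scatter.** An IRF-shaped column with free amplitude IRFAS(ω) describes
the intense dispersive feature at the solvent Raman line; it is constrained
to zero above a mask threshold (1100 cm⁻¹ in the preset) and omitted
entirely from TA surfaces.

## Estimation: variable projection

For any value of the nonlinear parameters θ (channel rates, μ₀, d_p, σ,
ω_n, γ_n) the spectra are conditionally linear and are solved per pixel by
a rank-revealing least-squares solve (SVD pseudoinverse, relative cutoff
1e-10, minimum-norm tie-break — duplicated or fully damped columns degrade
gracefully).  The nonlinear optimizer (trust-region-reflective
`scipy.optimize.least_squares` on the stacked, per-dataset-weighted
residual vector) therefore sees only θ.  Rates and damping constants are
optimized as logarithms, which keeps them positive without active bounds;
centers and dispersion coefficients are linear.  Linked parameters map to a
single free value.  Standard errors come from the projected Jacobian at the
optimum (`s²(JᵀJ)⁻¹`, chain-ruled back through the log transform); derived
quantities (lifetimes 1/Σk, branching fractions k_i/Σk) get linearized
(delta-method) standard errors.

**Rank-deficient nonlinear directions.** A branched target scheme contains
parameter combinations the data cannot determine: rescaling the branching
into a spectrally *free* state (or into the dark ground state) rescales a
population column that its own free spectrum compensates exactly, leaving
the model subspace — and hence the residual — unchanged.  The objective is
exactly flat along such directions, and an unregularized trust-region step
drifts arbitrarily along them (the numerical null-space columns of the
finite-difference Jacobian are pure noise).  `fit(anchor=a)` therefore
extends the minimum-norm policy of the linear stage to the nonlinear stage:
the residual vector is augmented with `a·(x − x₀)` in internal coordinates,
selecting the point of the optimal manifold nearest the starting values.
`a` must be negligible against the data residuals; the recovery experiments
use `a = 0.03` against data residual norms of order 10²–10³ (the induced
bias on determined directions is < 1e-4 relative).  The consequence is
stated plainly: *recovered branching fractions test the estimator's
consistency — that the fit does not corrupt a quantity the data leave free —
not data-driven identifiability.*  The eigenvalues of `K` (the lifetimes),
the IRF and the oscillation parameters are genuinely data-determined.

**Two-stage recovery protocol.** The recovery experiments follow the
standard workflow for target analysis: a loss-free sequential cascade
(global analysis) is fitted first, which pins the decay eigenvalues and IRF
precisely; the target scheme is then fitted from starts whose
per-compartment total rates are rescaled to the pre-fit eigenvalues while
branching ratios keep their perturbed starting values.  This avoids the
long traversal from strongly perturbed starts during which flat directions
would otherwise accumulate drift, and removes the occasional
label-permutation local minimum.

## The synthetic preset

No measured surfaces are deposited with the methodology this package
implements, so a full preset emulates the study conditions:

- **Scheme** (7 compartments, rates in ns⁻¹): S2 →(1/71 fs) S1vh →(1/175 fs)
  S1h; S1h splits 75%/25% between S1 and the ground state with total
  lifetime 0.8 ps; S1 (lifetime 3.3 ps) splits 64% to S*, 14% to the slow
  subpopulation S1′, a fixed 5 ns⁻¹ to the triplet, remainder to the ground
  state; S1′ decays with 5 ps (195 ns⁻¹ to GS + 5 ns⁻¹ to T), S* with
  6.7 ps; T is long-lived.  The rates are reconstructed from these printed
  lifetimes and fractions, with the S1→GS channel taking the remainder so
  the fractions are exact by construction.  The narrative around the hot-S1
  decay admits two readings (a 0.8 ps phase with 25% loss vs a 1.63 ps
  lifetime); the preset uses the 0.8 ps total so the target scheme's
  eigenvalues coincide with the sequential lifetimes and "the 0.8 ps
  phase" is well defined.
- **Sequential preset**: lifetimes 71, 175 fs, 0.8, 3.3, 5.9 ps, long-lived.
- **Spectra**: stylized Gaussian-band SADS.  FSRS: ground-state bleaches at
  the carotenoid ν₁/ν₂/ν₃ positions (≈1520, 1160, 1010 cm⁻¹) with an
  excited-state ν₁ band upshifting toward 1800 cm⁻¹; S1′ has spectra
  identical to S1 (equality *emerges* in the generator; the fit gives S1′
  its own column and does not impose it).  TA: bleach structure at
  450/480/510 nm with excited-state absorption at 545–565 nm.  No numeric
  spectra are published, so band positions/amplitudes are free stylization;
  recovery tests target the nonlinear parameters and component-matrix
  reconstruction, never absolute band amplitudes.
- **Coherent artifact**: three backward oscillations at 913 (solvent), 1154
  and 1511 cm⁻¹ (carotenoid ν₂/ν₁), damping 2.0/1.7/1.4 ps⁻¹ (the ≈1 ps
  Raman-pulse/linewidth scale), Lorentzian-like DOAS profiles (width 25
  cm⁻¹) with slowly varying phase, amplitude ≈5× the population peak.
- **IRF**: FSRS fwhm 180 fs with quadratic dispersion (d₁ = 0.03, d₂ =
  −0.004 ps per scaled unit, reference 1300 cm⁻¹), one width shared by
  Stokes and anti-Stokes; TA fwhm 97 fs, no dispersion (dedicated TA data
  treated as chirp-corrected).
- **Axes**: 421 delays, linear −1…1 ps then log-spaced to 100 ps; Stokes
  750–1900 cm⁻¹ (default 576 pixels); TA 420–770 nm.  Anti-Stokes reuses
  the Stokes structure with inverted raw sign.
- **Noise**: iid Gaussian, σ = 0.05 mOD — a realistic noise floor for
  averaged mOD-scale surfaces and one at which the published ≈10% parameter
  precision is meaningful.

What the generator does *not* emulate: probe-fluctuation structure,
shot-noise heteroscedasticity, baseline wander, pixel-to-pixel gain
variation, or physically derived Raman lineshapes.  Passing recovery tests
therefore demonstrate the estimator's correctness and precision under the
assumed noise model, not robustness to real-data systematics.

## Problem sizes and numerical choices

Recovery experiments run 10 independent perturbed-start fits each at
reduced pixel counts — TA 64 pixels for the target experiment, 32 for the
sequential one, FSRS 64 pixels, always the full 421-delay axis — chosen so
a full experiment completes in minutes on one
CPU while leaving the per-parameter information content ample (each fit
still uses ≈27k–54k residuals for ≈9–11 free parameters).  Perturbations:
rates, widths, damping ×U(0.8, 1.25); frequencies ±10 cm⁻¹; centers
±0.02 ps.  Finite-difference step 1e-4 (relative, internal coordinates) for
the recovery fits — large enough that Jacobian cancellation noise cannot
excite the flat directions, far below the scale of model curvature.
Optimizer tolerances 1e-8; eigenvalue degeneracy below 1e-9 ps⁻¹ is refused
with an actionable error (the preset schemes are well separated; confluent
exponential forms are deliberately out of scope).

## Known limitations

- Branching fractions into spectrally free or dark states are not
  data-identifiable (see above); reported values are minimum-drift
  estimates anchored at the start.
- Single-Gaussian IRF only; no exponential tails or multi-Gaussian shapes.
- Per-dataset scalar weights; no per-pixel weighting.
- The EADS transform assumes distinct eigenvalues and a diagonalizable `K`.
- The CA/scatter split below the scatter mask threshold is ill-conditioned
  (both model a narrow feature at the IRF); their *sum* is well determined,
  and the decomposition additivity is exact regardless.
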