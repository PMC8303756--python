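# Methods

## Model and assumptions

The spheroid is treated as a continuum of cells with concentration
C(r, t) on a ball of radius R(t). A Darcy-type closure (cell flux down the
pressure gradient, pressure proportional to concentration) gives a linear
reaction–diffusion equation ∂C/∂t = K∇²C + ηC; the moving boundary
follows the local flux, dR/dt = −K ∂C/∂r at r = R(t). Cell–cell adhesion
enters only through the Dirichlet condition C = C₀ at the surface: C₀ is
the "relaxed" concentration at which adhesive and pressure forces balance.
The model assumes radial symmetry, no nutrient limitation (appropriate to
small, early-stage aggregates — every cell is assumed oxygenated, so the
source is linear with a constant rate η), and no mechanical stress field.
It describes the formation phase only; once hypoxia or necrosis set in
(experimentally after roughly 160–180 h for glioblastoma spheroids of this
size) the homogeneity assumption fails and the model is expected to drift
from data.

Concentration units: the equations are linear in C and the radius ODE is
written for a dimensionless concentration; only the ratio C₀/Cᵢ is
physically meaningful. All public entry points therefore normalize
parameters to Cᵢ = 1 on entry, and multiplying C₀ and Cᵢ by a common
factor leaves every output unchanged (tested to machine precision).
Internal units are centimetres and hours; motility quoted in cm²/s is
converted once on input (K₀ = 10⁻¹⁰ cm²·s⁻¹ = 3.6·10⁻⁷ cm²·h⁻¹).

## Parameters

| parameter | units | default / typical | meaning |
|---|---|---|---|
| K | cm²/h | 3.6·10⁻⁷ (K* = 1) | motility: response of cell flux to concentration gradient, reduced by adhesion |
| η | 1/h | 0.016–0.020 (η* = 1.6–2) | proliferation rate; measured independently from paired counts as (N₂−N₁)/(24 N₁) |
| C₀/Cᵢ | — | 1.5–2 | relaxed-to-initial concentration ratio; >1 means contraction |
| R₀ | cm | 0.01–0.02 | initial (first-image) radius |
| t_max | h | 210 | observation horizon; also the time normalization |

ε and D (with K = εD, 0 < ε < 1) are carried as optional metadata and
validated for consistency, but the dynamics use K directly — no value of ε
is ever needed.

## Numerical scheme

The moving domain is mapped to the unit interval, r̄ = r/R(t̄),
t̄ = t/t_max, giving

  ∂C/∂t̄ = λ(t̄)[(2/r̄)∂C/∂r̄ + ∂²C/∂r̄²] + ητC,  λ = τK/R(t̄)²,
  dR/dt̄ = −λR ∂C/∂r̄|₁.

The discretized equation is exactly this mapped form. The chain rule on a
moving mesh additionally generates a convective term
(r̄/R)(dR/dt̄)∂C/∂r̄; it is not part of the default equations but can be
switched on (`include_mesh_advection=True`) for sensitivity studies — at
the reference conditions it shifts the radius trajectory at the few-percent
level, so the default and the chain-rule-complete variants are genuinely
different discretizations of the physical problem.

Choices, in brief:

* θ-weighted (Crank–Nicolson at θ = 0.5) time stepping; tridiagonal
  banded solves. Defaults n_nodes = 201, dt̄ = 10⁻⁴ (10⁴ steps for a full
  run, a couple of seconds).
* Center singularity: (2/r̄)∂C/∂r̄ → 2∂²C/∂r̄² by symmetry/L'Hôpital; the
  center row is 6(C₁−C₀)/Δr̄², second-order with the ghost-node symmetric
  stencil.
* Boundary gradient: three-point one-sided stencil, exact on quadratics.
* Coupling of λ(R): lagged at the old time level by default (preserves the
  tridiagonal structure); the radius update is a Heun-type θ-weighted rate
  with a predictor for the new-level coefficient. A Picard fixed-point
  option (tolerance 10⁻¹⁰, ≤ 50 iterations) quantifies the splitting
  error: ~10⁻³ relative at dt̄ = 10⁻³, shrinking with dt. Convergence
  studies use the Picard coupling; with it the coupled solver
  self-converges at order ≈ 2 on smooth regimes. On a frozen domain the
  scheme is order 2.0 against a manufactured solution
  C₀ + a·e^{−bt̄}·sin(πr̄)/r̄ (an eigenfunction, so the forcing is
  elementary).
* The physical initial data are discontinuous at the surface when
  Cᵢ ≠ C₀ (the boundary node takes C₀ from the first step, no smoothing).
  This corner limits the observed self-convergence of the *coupled*
  trajectory with physical data to order ~1.3; the order-2 claims are for
  smooth regimes, which is where the order of a scheme is meaningfully
  measured.
* Positivity is monitored, never enforced: concentrations below −10⁻¹²
  warn or raise, because clipping would mask an instability.
* The uniform relaxed state (C ≡ C₀, η = 0) is preserved to machine
  precision over 10⁴ steps (measured drift ~10⁻¹³ relative).

## Analytic solution family

The analytic route is quasi-static: the auxiliary constant-source problem
(∂C₁/∂t = K∇²C₁ + ηCᵢ with the same data) is expanded in Dirichlet
eigenfunctions sin(λₙr)/r, λₙ = nπ/R₁(t), with the eigenvalues frozen at
the evaluation time, and lifted to the full equation by the growth
transform C = e^{ηt}C₁ − η∫₀ᵗC₁e^{ητ}dτ. Here R₁(t) is the diffusion-only
reference radius

  R₁(t) = R₀ + (Cᵢ−C₀)·√(K/ηCᵢ)·erfi(√(ηCᵢ·t)),

the short-time boundary-layer solution (its η → 0 limit is the planar law
R₀ − 2(C₀−Cᵢ)√(Kt/π)). Its validity window is Kπ²t/R₀² ≲ 1; against a CN
solve of the constant-source system it agrees to ~2% at 5 h and ~5% at
10 h at the reference conditions, and diverges beyond the window (it keeps
contracting where the true solution saturates). Downstream uses floor R₁
at 0.1·R₀ once it has collapsed past the window.

Three levels of reduction are provided:

1. **Full eigen-series rate.** The boundary flux of the transformed modal
   solution, with the spatial shape factor
   F(R, n) = (R̄cosR̄ − sinR̄)/R², R̄ = nπR/R₁, evaluated at the current
   radius. Per-mode time integrals are taken in closed form (single
   exponents — no quadrature and no overflow at large ητ). The constant
   part of the series converges only algebraically (1/n²), so the tail
   beyond the truncation is summed in closed form via alternating
   Fourier–Bernoulli sums (π²/12 − θ²/4 and relatives), leaving an
   O(1/n⁶) remainder; doubling n_terms from 100 to 200 changes the rate
   by ~10⁻¹³ relative. A true bound on the dropped remainder is checked
   against `tail_tol` and warned on violation.
2. **Simplified (separation-of-timescales) rate.** R̄ ≈ nπ collapses the
   mode index out of the spatial factor; what remains is a history
   integral of the mode-sum over R(τ). Exact when η is slow compared with
   the diffusive relaxation rate K(π/R₀)² (verified: the gap to the full
   series shrinks as that ratio is reduced). The source part of the
   collapsed sum has the exact value −R₀ηCᵢR₁²/3K.
3. **Elementary closed form.** Freezing R(τ) ≈ R₀ and replacing the
   eigen-sum by its short-time theta-function asymptotic gives
   R(t) = R₀ + α[(t − 1/2η)erfi(√(ηt)) − √(t/πη)e^{ηt}], α = (C₀−Cᵢ)√(Kη):
   contraction, an interior minimum whose time depends only on η (so the
   higher-η reference set bottoms out earlier), then growth. This is a
   *rough* formula: it shares only the leading planar behaviour with the
   integrated simplified rate and deviates from it by tens of percent in
   mid-trajectory — the gap is model reduction, not quadrature, and does
   not close as tolerances tighten.

Series and data are incompatible at t = 0 when Cᵢ ≠ C₀ (Gibbs-type
transient from the surface discontinuity), so rates are clamped to
t ≥ 10⁻³·t_max and take the one-sided limit earlier; with compatible data
(Cᵢ = C₀) no clamp is applied and the initial flux is exactly zero.

**Exact η = 0 solution.** Without proliferation the mapped system (as
discretized, i.e. advection-less) reduces under the rescaled diffusion
time s(t), ds/dt = K/R², to fixed-domain diffusion on the unit ball:

  R(s) = R₀·exp(−2(C₀−Cᵢ)Φ(s)),  Φ(s) = Σₙ(1−e^{−n²π²s})/(n²π²) → 1/6,

with t(s) recovered by one quadrature. The radius plateaus at
R₀e^{−(C₀−Cᵢ)/3}; the short-time limit is the planar law above. The CN
solver converges to this curve under refinement (deviation ~4·10⁻⁵
relative at default resolution, inside the measured discretization
error), which is the strongest available end-to-end check of the coupled
scheme.

**Analytic vs numeric.** Integrating the simplified rate (default; the
full series behaves nearly identically) and comparing with the CN solver
on the two reference sets (η* = 1.6, C₀/Cᵢ = 1.5, R₀ = 0.01 cm and
η* = 2, C₀/Cᵢ = 2, R₀ = 0.02 cm): the contraction-phase discrepancy is
~0.8% of radius, and the growth-phase discrepancy is ~80% — the analytic
family is a contraction-phase tool and deliberately degrades once growth
dominates (the R̄ ≈ nπ and frozen-eigenvalue assumptions fail there).
Retaining the exact constant-source particular terms in the modal
coefficients is essential to this contraction-phase accuracy.

## Synthetic data

`synthesize_trajectory` emulates the formation imaging experiment: the CN
solver generates the true radius; it is sampled at the imaging cadence
(default 20 frames over 210 h — the first at t = 0, taken as the first
image ~5 h post-seeding, then every 5–24 h, denser early while the
contraction is fast); multiplicative Gaussian noise radius·(1+ε),
ε ~ N(0, sd²) with sd = 2% by default, models image-derived size error;
diameters (2R) are reported to mirror the measured observable. What this
does *not* emulate: shape irregularity (the d_max/d_min averaging rule is
supported on input but noise is applied to the mean size directly),
replicate-to-replicate biological variability, the late-time (>160 h)
breakdown of model validity, and any drift or autocorrelation in imaging
error. Passing recovery tests therefore demonstrate estimator correctness
under the stated noise model, not robustness to model misspecification.

## Calibration

Bounded trust-region least squares on relative radius residuals
(multiplicative noise makes relative residuals the maximum-likelihood
weighting), positive parameters on a log scale. R₀ is anchored to the
first observed radius rather than fitted — it is directly observed, and
fitting it jointly measurably does not improve the other parameters. When
an independent count-based η estimate exists, fixing η and fitting only
(K, C₀/Cᵢ) mirrors the experimental workflow and improves conditioning.
The objective has a secondary basin along the sloppy K–C₀/Cᵢ direction, so
the optimizer also runs from a data-driven start (η from the late growth
tail via R ~ e^{ηt/3}; C₀/Cᵢ from the time of minimum via η·t_min;
K from the contraction depth via the planar law) and keeps the better
fit. Uncertainties are Gauss–Newton (local quadratic) standard errors on
the log scale.

Forward solves inside the fit run at 81 nodes, dt̄ = 10⁻³: the resulting
parameter bias is ~0.3%, far below measurement-induced spread, at ~10× the
speed of the reporting resolution.

Measured estimator behaviour (20-point cadence): noiseless data invert to
~10⁻¹⁰ relative from the data-driven start and ≤1% from 2×-perturbed
starts; at 2% noise, the median error over 20 replicates at the center of
the studied parameter ranges (K* = 2, η* = 1.8, C₀/Cᵢ = 1.75) is ~3–4% for
η and C₀/Cᵢ and ~8–14% for K — K is the sloppy direction (it is informed
mainly by the handful of contraction-phase points, whose total excursion
is a few times the noise), and this spread is at the information-theoretic
floor for the stated noise, not an optimizer artifact. With observations
restricted to the contraction phase only, the η uncertainty blows up by
more than an order of magnitude — growth-phase data are what identify η.

## Known limitations

* The analytic family (including R₁ and the elementary closed form) is
  quantitative only in the contraction phase; outside it, use the solver.
* The default discretization omits the mesh-advection term so as to solve
  the mapped equations exactly as posed; enable the flag to quantify the
  difference (a few percent at reference conditions).
* The lagged coupling's O(dt) splitting error is negligible at default
  dt but caps measured convergence order below 2 in coupled refinement
  studies; use Picard coupling for such studies.
* No nutrient/oxygen field, necrotic core, mechanical stress, or drug
  effect; single spheroid per fit (no hierarchical pooling).
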