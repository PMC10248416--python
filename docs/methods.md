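# Methods

## Scope and data model

The package reproduces the analysis chain of a liver-DWI biomarker study:
voxel decays S(b) over b = 0, 200, 600, 1000, 2000, 3000 s/mm² (1/1/1/2/4/6
signal averages), five parametric signal models, whole-tumor VOI means read
by two raters, and patient-level statistics comparing 46 VETC-negative with
40 VETC-positive hepatocellular carcinomas. Raw images are not public, so
all inputs are synthetic: a patient-level cohort sampler and an image-level
phantom generator, both first-class and tested.

## Units

b is accepted in s/mm² and scaled internally by 1/1000 to ms/μm², making
b′·D dimensionless with diffusivities in μm²/ms (the units the study reports
for ADC, DKI_D, SEM_DDC, FROC_D, CTRW_D). FROC μ is in μm; all exponents
(K, α, β) are dimensionless.

## Mittag-Leffler evaluation

E_α(z) on the negative real axis (0 < α ≤ 1) switches between:

1. the power series Σ z^k/Γ(αk+1), used only while its largest term stays
   below 3·10⁴ (keeping double-precision cancellation under ~1e-9) and its
   tail has decayed within 420 terms;
2. Pollard's complete-monotonicity integral
   E_α(−x) = sin(απ)/(απ) ∫₀^∞ e^{−(ux)^{1/α}} / (u² + 2u·cos απ + 1) du
   on deterministic composite Gauss-Legendre panels for α ∈ [0.05, 0.95].
   Panels are laid out geometrically from the integrand's decay scale
   u ≈ 1/x, refined around the near-pole point u = 1 (the denominator's
   complex poles sit on the unit circle at distance sin απ from the
   contour), and further refined around the cutoff u = 46^α/x when α < 0.35,
   where the decay becomes cliff-like (relative width ~8α);
3. adaptive vector quadrature (`scipy.integrate.quad_vec`, breakpoint at
   u = 1) for α outside [0.05, 0.95], where the peak at u = 1 narrows like
   sin απ.

Validated against an arbitrary-precision oracle (series at adaptive
precision where conditioned, else mpmath tanh-sinh quadrature at 40 digits)
and against the closed forms E₁ = exp and E_{1/2}(−x) = e^{x²}erfc(x):
worst observed absolute error ≈ 2·10⁻¹⁰ over α ∈ [0.05, 0.999],
x ∈ [0, 100]. α = 1 is special-cased to exp.

## Fitting

Per decay: bounded trust-region least squares (`scipy.optimize.least_squares`,
method `trf`) on signals normalized to unit maximum, with s0 always free
(S(0) is itself noisy) and residuals weighted by √(averages per b) — points
averaged n times have variance σ²/n. Bounds: diffusivities [0.01, 5] μm²/ms,
K [0, 3], α/β [0.1, 1], μ [0.5, 20] μm; these bracket all published values
with wide margins. ADC is fitted on the b = 0/600/1000 subset only; the
non-Gaussian models use all six b-values. No Rician-bias correction is
applied (none is described for the source analysis); the phantom's noise
level and averaging are the main defense.

Start strategy. DKI/SEM use fixed 3-point grids on their nonlinear
parameter. The CTRW objective has genuinely separated local minima (a
small-α/large-D decay can be mimicked to ~0.1% by a mid-α/mid-D one), so a
fixed 3-point grid provably misses basins: starts are instead ranked by a
deterministic coarse profile — a 9×8 (α, β) grid with D profiled over a
14-point log grid and s0 solved linearly — and up to 16 candidates seed the
local solver, with early exit once a start is numerically exact (SSE below
1e-19 of the normalized scale) and a cap of 8 starts when the data are
noisy (extra precision is meaningless there). Near-exact CTRW fits end with
a short Nelder-Mead creep: the SSE valley is curved and nearly flat, the
trust-region solver stalls on xtol partway along it, and the simplex
recovers several further digits. With this machinery, 200 uniform in-bounds
zero-noise draws are recovered to ≤1e-5 relative error for MONO, DKI, SEM
and CTRW (worst observed ≈ 5·10⁻⁷).

FROC identifiability. With G_d back-solved from b at one (Δ, δ) pair, the
FROC exponent is exactly −A·b′^β with A = D·μ^{2(β−1)}·(Δ−c_βδ)/(Δ−δ/3)^β,
c_β = (2β−1)/(2β+1). D and μ enter only through A: they are exactly
degenerate, not merely weakly identified. The fit therefore estimates the
identifiable triple (s0, A, β) and reports (D, μ) on the equivalence ridge
with μ fixed at a reference 3.5 μm (falling back to adjusting μ if the
implied D leaves its bounds, with a flag). β, s0 and A are recovered to
1e-5 on zero-noise draws whenever the decay is informative; per-parameter D
and μ recovery is impossible by construction and the corresponding strict
acceptance check is intentionally left failing with this analysis.

DKI validity: the quadratic exponent rises for b′ > 3/(DK); forward
evaluation beyond the bound warns, and fits whose estimates imply a
violation at the largest b are flagged (`dki_validity_bound`).

## Synthetic cohort

Patient markers are truncated normal draws (rejection sampling) with the
published per-group means/SDs for all 11 markers; truncation bounds are the
fitting bounds, keeping α, β ≤ 1 physical. Only marginal summaries are
published, so markers default to independent; a positive-definite
correlation matrix hook exists, and any quantity that depends on the joint
distribution — notably the combined logistic model's AUC — inherits this
unknown (with independent markers the simulated combined AUC exceeds the
published 0.747, as expected when correlation is ignored). Rater 1 is the
latent draw; rater 2 adds zero-mean noise with SD = 0.3× the marker's group
SD, a value chosen once to land ICC(2,1) in the published "good/excellent"
range (~0.9–0.96) and not revisited; setting it to 0 makes ICC exactly 1.

The phantom embeds an ellipsoidal lesion (any generating model) in a
background tissue; per b, each stored voxel value is the mean of
`averages(b)` independent Rician magnitudes √((S+ε₁)² + ε₂²),
ε ~ N(0, σ·s0). Rater 2's mask flips a seeded 10% of inner- and
outer-boundary voxels (default Dice ≈ 0.85–0.9 against rater 1 for the
default 64-voxel lesion). The generator emulates decay shapes, averaging
variance (SD ∝ 1/√n), the Rician floor σ√(π/2) at zero signal, and
independent-delineation jitter; it does not emulate anatomy, cirrhotic
texture, breathing motion or EPI distortion — a green phantom test
establishes correctness of the estimation chain, not scanner realism.

## Statistics

* Group comparison: per-group Shapiro-Wilk at α = 0.05 gates an equal-
  variance two-sided t-test vs a two-sided Mann-Whitney U (the source
  analysis names the two tests but not its normality test; the gate is
  recorded in the output).
* Categorical: Pearson chi-square, Yates continuity correction exactly when
  some expected count < 5.
* ICC: ICC(2,1) — two-way random effects, absolute agreement, single
  measure — with the F-based Satterthwaite 95% CI (McGraw & Wong case 2);
  cross-checked against pingouin. Bands: poor < 0.50, moderate 0.50–0.75,
  good 0.75–0.90, excellent > 0.90.
* Logistic combination: unpenalized ML (statsmodels Newton/IRLS, tol 1e-10);
  complete separation is flagged, never silently reported as converged. The
  significance gate for entering the model is two-sided p < 0.05 on the
  rater-averaged markers.
* ROC: decision rule "score ≥ threshold", AUC = normalized Mann-Whitney U
  with ties counted ½ (identical to trapezoidal integration of the
  tie-aware curve), Youden-maximal cutoff with ties broken toward higher
  specificity, accuracy = (sens·n_pos + spec·n_neg)/n. AUC CIs are normal
  approximations with the DeLong variance, truncated to [0, 1]. Combined-
  model cutoffs live on the predicted-probability scale, single-marker
  cutoffs on the native marker scale.
* DeLong: midrank structural components, covariance of paired AUCs,
  two-sided z-test; degenerate zero-variance differences flagged with p = 1.
* Binormal AUC Φ(|μ₊−μ₋|/√(σ₊²+σ₋²)) is provided as an analytic
  cross-check that published group distributions and published AUCs are
  mutually consistent (0.55±0.08 vs 0.61±0.09 → 0.691, published 0.678).

## Pipeline

`run_study` chains screening arithmetic (159 recruited − six exclusion
counts = 86 included), cohort simulation, ICC, comparisons, the gate,
logistic combination, ROC tables and the DeLong matrix; a seed fully
determines every output byte, and the written bundle includes a YAML config
echo sufficient to reproduce it. The equation layer is usable standalone on
plain (b, signal) CSV tables and NIfTI volumes via `vetcdiff.io`.

## Known limitations

* FROC D and μ are reported by ridge convention (above); absolute μ values
  are not comparable across timing conventions.
* CTRW exponent recovery at the extreme flat corner (α, β both near 0.1
  with large D) approaches the double-precision information limit; the
  deep-start machinery recovers all tested draws, but curves there differ
  by ~1e-7 relative and small perturbations matter.
* The combined-model AUC depends on the unpublished inter-marker
  correlation; with the default independence it is optimistic.
* In-sample ROC only, as in the source analysis: no cross-validation.
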