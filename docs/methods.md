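# Methods

## Model

Each twin pair contributes a 4-vector of latent liabilities
(Sz₁, BV₁, Sz₂, BV₂): a disease liability and a quantitative-trait
liability per member, jointly multivariate normal with unit variances.
A bivariate Cholesky factorization generates the structure: additive
genetic (A), common-environment (C) and unique-environment (E) factors of
the disease load on both traits through common paths
(a_c, c_c, e_c; a′_c, c′_c, e′_c), and trait-specific factors add
(a_s, c_s, e_s). A-factors correlate 1 across MZ and ½ across DZ
co-twins, C-factors 1 in both, E-factors 0. The implied covariance
entries are

* within person, cross trait: a_c·a′_c + c_c·c′_c + e_c·e′_c
* cross twin, disease: α·a_c² + c_c²
* cross twin, trait: α·(a′_c² + a_s²) + (c′_c² + c_s²)
* cross twin, cross trait: α·a_c·a′_c + c_c·c′_c

with α = 1 (MZ) or ½ (DZ). Disease status is the liability dichotomized
at the prevalence threshold; the trait is observed as an ordinal variable
with K − 1 free thresholds shared across members, zygosities and
affection groups.

Assumptions inherited from the classical twin design: no assortative
mating, no gene–environment interaction or correlation (both assumed
zero), equal environments across zygosities, no sex limitation.

## Ascertainment correction

Samples recruited through affected probands are uninformative about the
disease margin. Instead of modelling the selection event, the disease-side
parameters are fixed to external population values: h² = .81, c² = .11,
e² = .08, hence MZ/DZ disease liability correlations .92/.515, and a
threshold at the 1% prevalence quantile. No Pr(ascertainment) denominator
enters the likelihood; the correction operates entirely through these
constraints, which is also why every report repeats them. The trait-side
parameters and the cross-trait structure remain free.

## Estimation

**Likelihood.** Full-information maximum likelihood over the observed
ordinal cells. Complete pairs contribute the 4-dimensional normal
rectangle probability of their (affection₁, class₁, affection₂, class₂)
cell; singletons contribute the bivariate (affection, class) rectangle;
a missing ordinal class marginalizes to an infinite slab. Cells are
pooled over the member-exchange symmetry the model imposes. A populated
cell with non-positive model probability yields −∞ (a boundary signal,
not an exception).

**Rectangle probabilities.** Bivariate rectangles use the closed form via
Owen's T function (machine precision; the documented contract is 1e-10).
Four-dimensional rectangles use sequential conditioning: the two ordinal
slab dimensions are conditioned on through a fixed scrambled-Sobol rule
and the two (half-infinite) disease dimensions are then integrated in
closed form as a conditional bivariate normal. For generic rectangles the
public `mvn_rect` permutes variables so the two widest intervals are the
exactly-integrated pair; at the default 2¹⁷-point rule the absolute error
is ~1e-8 (verified against closed-form products and a seeded
high-precision reference). The likelihood loop uses the same scheme with
a fixed (BV₁, BV₂, Sz₁, Sz₂) ordering at 512 nodes, where typical cell
errors are 1e-8–1e-7. The Sobol rule is generated once from a fixed
internal seed: every probability, hence every fit, is bit-reproducible.

**Parameterization.** Polychoric fit: the five free correlations on an
atanh scale; ordinal thresholds as first threshold plus log-increments
(ordering enforced by construction). ACE fit: the five free paths
(a′_c, c′_c, e′_c, a_s, c_s) directly, with e_s recovered as the positive
root of the unit-variance constraint and a large smooth penalty when the
root would be imaginary; paths are unconstrained in sign, and the reported
r_g sign follows a′_c. Non-PSD correlation proposals are rejected by the
Cholesky factorization and penalized.

**Optimization.** L-BFGS-B with numerical gradients from two
deterministic starts — a neutral start and a moment-based start (crude
product-moment twin correlations; Falconer transforms
h² = 2(r_MZ − r_DZ), c² = 2r_DZ − r_MZ for the ACE fit) — keeping the
better optimum. Ordinal-threshold starts come from the pooled category
frequencies. Convergence status, iteration count and the optimizer
message are part of every `FitResult`.

**Confidence intervals.** Profile likelihood at the χ²(1) 95% cutoff
(−2ΔlnL = 3.84): the target parameter is stepped outward from the MLE,
nuisance parameters re-optimized warm-started, and the crossing solved by
Brent's method; endpoints are mapped back through tanh for correlations.
Profiling is requested per parameter (`ci=["r_within"]`) because each
endpoint costs several constrained refits. Variance-component null
hypotheses sit on the boundary of the parameter space, so the
likelihood-ratio test against a dropped component reports the nominal
χ² p-value with an explicit conservativeness caveat (the asymptotic
reference is a chi-bar-square mixture).

## Preprocessing

The observed trait is residualized by OLS on an intercept, a single
Helsinki-site indicator (the site whose image-processing pipeline
differed), sex, age (linear) and intracranial volume, using all
individuals jointly; residuals are then cut at left-continuous empirical
quantiles into K = 5 classes on the pooled sample, ties going to the
lower class. Binning is monotone and invariant to positive affine
rescaling. A rank-deficient design raises an error naming the dependent
columns; fewer than K distinct values raises a degenerate-binning error.

## Synthetic cohorts

The simulator draws pair liabilities from the exact model-implied
4-variate normal (one numpy PCG64 generator per call, seeded from the
config), dichotomizes the disease at the prevalence threshold, and labels
covariates. Defaults mirror the study conditions: 1% prevalence, 5
ordinal classes, site mix proportional to the consortium totals
(186:38:132:328), age ~ N(38, 11.3²) shared within pair, sex shared
within pair, ICV ~ N(1450, 120²). Covariates are independent of the
liabilities by default, so residualization is a near-no-op; optional
linear `covariate_effects` add real confounding to the *observed* trait,
making the correction testable. The bundled cerebrum generating model
uses trait h² = .76, c² = 0, e² = .24 and r_g = −.21, with r_e solved so
the within-person correlation is exactly −.22.

Ascertainment schemes: `population` (no selection);
`proband_plus_controls` (every pair with an affected member plus control
pairs at the sampling frame's ≈1.9 control:case pair ratio, configurable);
`table1_frame` (fills the consortium frame's per-site cell counts —
concordant, discordant patient/co-twin, control — by consuming
randomly-ordered pairs of the right kind). Frame cells whose patient and
co-twin counts disagree, and odd individual counts, produce singletons:
pairs with one missing member, which the likelihood marginalizes (FIML).
Cell counts are invariant across seeds; an unsatisfiable cell raises an
error naming it.

What the simulator does **not** emulate: scanner and segmentation error
beyond the E component, age/sex effects on liability, site differences in
true prevalence, volunteer bias in control recruitment, and any matching
rule for control pairs beyond the frame counts. Parameter-recovery
results therefore validate the estimator under the model's own
assumptions, not robustness to their violation.

## Numerical choices and problem sizes

* Likelihood integration: 512 Sobol nodes per cell batch (see above);
  public `mvn_rect` default 2¹⁷ nodes.
* Optimizer tolerances: L-BFGS-B ftol 1e-10, gtol 1e-7, maxiter 300.
* Profile CI: bracket expansion step 0.05 (transformed scale), Brent
  xtol 1e-4, giving −2ΔlnL within 0.01 of 3.84 at reported endpoints.
* Boundary reporting: trait-side c² (or h²) below 1e-4 is flagged as a
  boundary solution; a zero component makes the matching factor
  correlation undefined (`None`), contributing exactly 0 to r_ph.
* Recovery runs use 5,000 pairs per zygosity — far more informative than
  the consortium's 684 individuals, chosen so parameter recovery is a
  sharp test of estimator correctness rather than of sampling noise; the
  suite's diagnostic of the 2:1 MZ:DZ cross-correlation ratio uses 20,000
  pairs per zygosity because the DZ denominator (≈ −.2) is otherwise too
  noisy to resolve 2:1 from 1:1.
* Degenerate inputs: prevalence outside (0,1), non-monotone thresholds,
  inverted rectangle bounds, non-PSD correlation matrices and
  over-occupied pair ids all raise typed errors (`twinace.exceptions`).

## Known limitations

* The polychoric and ACE fits assume the fixed disease-side values are
  correct; misspecifying h²/c²/e² biases the cross-trait decomposition.
* Profile CIs are one-parameter; joint confidence regions and CIs for
  derived standardized quantities (e.g. h²_BV from the path fit) are not
  provided — the paths themselves are profiled instead.
* No sex-limitation, gene–environment interaction, or >2-trait
  extensions; no Bayesian estimation; weighted-least-squares polychoric
  shortcuts are used only as starting heuristics, never as estimates.
* The AE submodel inflates r_g when a genuinely nonzero (if small) c²
  is forced to zero — reported, as is conventional, with the boundary
  caveat on its likelihood-ratio test.
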