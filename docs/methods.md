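# Methods

## Data preparation

Observations are long-format rows (individual × trial) holding five
open-field behaviors — track length TL (cm), % time active ACT, % area
covered AC, time in middle TIM (s), time out of refuge TOR (s) — a
binary post-strike emergence outcome emREF, and four waterborne steroid
release rates (pg/h): cortisol and 11-ketotestosterone before and after
each trial (F_PRE, F_POST, KT11_PRE, KT11_POST).

Behaviors are square-root transformed, hormones natural-log
transformed, and both rescaled to standard-deviation units: each
transformed trait is divided by its pooled sample SD (n−1 denominator,
computed over *all* non-missing observations, after any rows lost to
missingness). The mean is not removed — the model's mean fixed effect
absorbs it. On this scale the among-individual variance of a trait is
its repeatability, and no single behavior can dominate the
among-individual matrix through scale alone. Release rates are totals
scaled to pg/h; mass-scaling (`ln(rate/mass)`) is used only in the
waterborne-vs-whole-body validation correlation — the mixed models
control for mass as a fixed effect instead, which does not force a
proportionality assumption.

Missing data are dropped trait-wise: the multivariate model tolerates
different record counts per trait, which is exactly the situation when
one animal dies before the final trial.

## The mixed model and REML

For the stacked observation vector the covariance of two observations
is `[same individual]·I[t,t'] + [same record]·R[t,t']`. The REML
log-likelihood

    l_R = -1/2 [ (n-p) log 2π + log|V| + log|X'V⁻¹X| + y'Py ]

is evaluated block-wise per individual, with individuals grouped by
missing-data pattern so each unique within-individual covariance block
is factorized once (the balanced 20 × 5 design reduces to two
patterns). Fixed effects are profiled out by GLS at every step.

Covariance structures: `absent`, `diagonal` (log-SD parameters),
`unstructured` (log-Cholesky factor, which keeps every iterate a valid
PSD matrix), and for **I** additionally `unstructured_free` — a
symmetric but unconstrained parameterization in the convention of
classical REML packages, whose estimates may be indefinite. The free
form matters for bias: when the true **I** is singular or nearly so
(the empirical behavioral **I** has a zero eigenvalue after PSD
projection), a PSD-constrained estimator can only err "inward" on the
low-variance directions, inflating small repeatabilities at n = 20
(we measured +0.035 on a true value of 0.101 over 200 replicates).
The unconstrained fit removes this truncation bias; it is used in the
parameter-recovery study, while the PSD form remains the default for
the pipeline because every downstream consumer (correlations,
bootstrap, reports) is better behaved with a valid covariance matrix.

Optimization is quasi-Newton (L-BFGS-B) with analytic gradients
(derivative blocks are collapsed to trait-level k × k contractions per
missing-data pattern, so a gradient costs ~2–3 likelihood
evaluations). Three fixed multi-start initializations (among-individual
variance fractions 0.3, 0.05, 0.6 of each trait's sample variance)
guard against local optima and make fits deterministic; convergence
tolerances are `ftol 1e-12`, `gtol 1e-8`. The `unstructured_free` fit
is two-stage: the log-Cholesky optimum is found first, then refined
without the PSD constraint (the unconstrained surface has an
infeasibility cliff where the stacked covariance loses definiteness,
so cold starts are unreliable). Among-individual variances that
collapse below 1e-6 under a PSD parameterization are reported as exact
zeros with a boundary flag.

Sampling covariances of the covariance estimates come from the inverse
observed information (Hessian of the REML log-likelihood by central
differences of the analytic gradient), delta-method-transformed to the
covariance-element scale. Fixed-effect coding is treatment contrasts
(first trial / first stack as reference) with day order and mass
mean-centered per trait; covariance estimates are invariant to this
coding, fixed-effect values are not.

A brute-force oracle (`reml_loglik_oracle`) builds the full N × N
stacked covariance by looping over observation pairs and evaluates the
same REML expression with dense determinants. It shares only the
design construction with the fast path and is used to verify the
block-wise evaluation to 1e-6 on small instances.

## Model comparison

The hierarchy (1) no individual effect + diagonal R, (2) + diagonal I,
(3) + unstructured R, (4) + unstructured I is compared by LRTs with df
equal to the number of added covariance parameters (k, k(k−1)/2,
k(k−1)/2). Because a tested variance sits on its parameter-space
boundary, the univariate single-variance test uses the 50:50
`χ²₀/χ²₁` mixture; multivariate comparisons keep the conservative
plain χ². Statistics within 1e-6 below zero are clamped to zero.
Null simulations (V_I = 0) confirm the mixture p-values are
conservative-to-uniform (one-sided KS at 200 replicates).

Between-trial correlation matrices (the post-hoc short-horizon
repeatability check) residualize each trial's values on mass and day
order by OLS, then take pairwise-complete Pearson correlations across
individuals with the classical SE `√((1−r²)/(n−2))` and an `|r| ≥ 2SE`
significance flag. A joint mixed-model alternative would also be
defensible; the residualization route is the package default.

## Eigen decomposition and bootstrap

Eigenvectors of the symmetrized **I** are sorted by descending
eigenvalue and sign-stabilized (loading sum positive; ties resolved by
the first nonzero loading). Variance shares are eigenvalue/trace ×
100. Uncertainty: the k(k+1)/2 unique elements of **I** are redrawn
jointly from `MVN(vech(I), S)` (S = REML sampling covariance), each
draw is decomposed, each draw's first eigenvector is aligned to the
point estimate's by dot-product sign (preventing artifactual
bimodality), and per-trait 95% HPD intervals summarize the loading
distributions. Non-PD draws are not rejected — the symmetric
decomposition is still defined and rejection would bias the intervals
when the estimate sits near the PSD boundary — but their frequency is
reported. The HPD interval is the shortest contiguous window over the
sorted samples containing ⌈0.95·n⌉ points, leftmost window on ties; no
kernel smoothing, for reproducibility.

## Liability model for the binary trait

Emergence is modeled as `y ~ Bernoulli(logit⁻¹(l))` with latent
`l = x'β + u_i + e`, `e ~ N(0,1)` fixed (the residual variance is not
identifiable separately from the link). The logistic link contributes
π²/3 of latent variance, so the liability-scale repeatability is the
intraclass correlation `V_I/(V_I + 1 + π²/3)`, applied draw-wise to
the posterior.

The sampler is data augmentation: vectorized random-walk Metropolis on
the latent liabilities (step 1.8), conjugate Gaussian updates for fixed
and individual effects, conjugate variance updates. The univariate
model uses parameter expansion — `u_i = α w_i` with `α ~ N(0, 25)` and
a scaled-inverse-χ² (ν = 1) prior on `V_w` — which mixes well when
`V_I` is near zero and gives the reported `V_I = α²V_w` a
heavy-tailed, weakly informative prior. The bivariate binary–Gaussian
model (for among-individual correlations `r_I` between emergence and a
behavior) places a conjugate inverse-Wishart (df 3.002, scale identity)
on the 2 × 2 individual covariance; matrix-variate parameter expansion
was judged not worth its complexity at these data sizes. All priors
are arguments. Default run length is the fast preset (11,000
iterations, 1,000 burn-in, thin 10 → 1,000 draws); the production
preset (1,050,000 / 50,000 / 1,000) is available as `FULL_SETTINGS`.
Convergence is reported via split-chain R̂ and autocorrelation-based
effective sample size; posterior modes use a Gaussian KDE. An
observed-scale path (Gaussian REML on the raw 0/1 outcome) is provided
for comparison and warns that residual normality is violated.

## The synthetic-data generator

`simulate_study` draws trait vectors on the transformed SD-unit scale
from the mixed model itself — `u_i ~ MVN(0, I_true)` per individual,
`e_ij ~ MVN(0, R_true)` per trial — then back-transforms (squares
behaviors, exponentiates hormones) onto raw scales with realistic
locations (track length ≈ 900 cm, pre-trial cortisol ≈ 1,870 pg/h,
body mass ~ N(1.16 g, 0.073 g)), so the pipeline's transform and
scaling steps are genuinely exercised. Defaults encode the study
conditions: 20 individuals × 5 trials; the published behavioral
**I**/**R** estimates as generating truth (**I** projected to the
nearest PSD matrix — it is printed with a −3e-5 eigenvalue); hormone
matrices assembled from the reported repeatabilities (0.039–0.202),
the F_PRE–KT11_PRE among-individual correlation (0.768) and the
F_POST–KT11_POST within-individual correlation (0.356); one randomly
chosen fish absent from the final trial; fixed-effect sizes for trial,
stack and day order default to zero (none are reported). Emergence
comes from a liability with intercept −0.8 (≈ one-third prevalence),
individual variance 1.0 (IC ≈ 0.19, inside the reported credible
interval), and a 0.4 correlation with the activity individual effect
(the qualitative "emergers are bolder" pattern). Percent traits are
clipped to [0, 100] and square-root-scale values to ≥ 0; with the
default locations these bounds sit 3.5+ SDs from the mean, so clipping
is negligible.

What the generator does *not* emulate: assay noise mechanisms
(extraction efficiency, cross-reactivity), habituation trends in trial
means, heteroscedasticity across trials, or non-Gaussian tails. Tests
passing on these simulations therefore establish that the estimators
recover the assumed model's parameters at the study's design size —
not that real open-field data satisfy that model.

## Monte-Carlo scales and numerical choices

The acceptance suite runs 200 REML recovery replicates, 50 eigen-share
replicates and 20 liability-coverage replicates (200 individuals × 10
observations each, the size at which binary data carry useful
information about a latent variance); the standalone acceptance script
uses 30/30/4 replicates to keep a single run short — these sizes were
chosen as the package's own reporting scale and match the estimators'
behavior at the full test sizes. Tie-breaks and degenerate inputs:
zero-spread traits refuse to standardize; constant bootstrap samples
yield zero-width HPDs; LRT statistics are clamped at −1e-6;
correlations from indefinite matrices may leave [−1, 1] and are
returned with a warning rather than truncated.

## Known limitations

* Fixed-effect inference (Wald F with denominator-df approximations) is
  not implemented; the acceptance surface is variance components.
* No pedigree/animal models, autoregressive residuals, or random
  slopes.
* The bivariate liability sampler's inverse-Wishart prior is mildly
  informative near zero variance; with ~20 individuals, `r_I`
  posteriors are prior-sensitive (as they are in any tool at that n).
* Threshold models with more than two traits are out of scope.
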