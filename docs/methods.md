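# Methods

## Model

Each vital rate `Y` observed on colony `c` in observation unit `n` (a photo
interval, a cell-interval, a cell, or a survey-night cohort) is modeled as

    g(E[Y_n]) = β₀_c + Σₓ β(s_x) W_{n,x} (+ log d_n),

with `W_{n,x}` the number of workers in IT-span bin `x` present in the
relevant lagged window, `β(s)` a smooth size-specific per-capita slope,
fixed colony intercepts `β₀_c`, and an exposure offset `d_n` (days between
photographs) for egg counts.  Families: negative binomial (log link, NB2)
for egg counts and development time; binomial (logit) for daily larval
survival coded as interval day-trials — `d` successes for a surviving cell,
`d−1` successes and one failure for a cell that died, so successes plus
failures always equal the interval length; Gaussian (identity) for mean and
CV of callow size.

Lag conventions: egg production and survival use the previous week's
composition; development time and the callow-size channels use the mean
composition over the relevant development window.  The development-window
mean includes surveys on both endpoints of the cell's clump-to-eclosion
span; callow cohorts use the surveys in the 14 days before (not including)
the cohort's survey night, approximating the unobserved individual
development windows by the typical ~14-day egg-to-eclosion time.

## Basis, penalty, fitting

`β(s)` uses a natural cubic regression spline in the value-at-knot
(cardinal) parameterization with 2–5 equally spaced knots over the size
grid; the penalty is the exact integrated squared second derivative of the
interpolant, whose null space is the linear functions.  The penalty matrix
is rescaled to unit mean nonzero eigenvalue so smoothing parameters are
comparable across grids and the penalized normal equations stay well
conditioned.

Fitting is penalized IRLS with fixed initialization from the grand-mean
null model.  Convergence requires a relative deviance change below 1e-8
together with a relative coefficient step below 1e-8 (or a sustained
deviance plateau); the cap is 200 iterations and a binomial linear
predictor beyond ±30 is treated as separation.  A ridge of 1e-10 times the
mean diagonal is added to the normal equations so rank-deficient designs
(e.g. unpopulated bins in the univariate age smooth) remain stable; this
perturbs identified coefficients far below reported precision, and the
single-bin zero-penalty fit still matches an independent GLM solver to
better than 1e-6 relative error (tested).

The smoothing parameter is chosen by generalized cross-validation
(`n·deviance/(n−EDF)²`) on a 27-point log grid over [1e-6, 1e7] with a
bounded golden-section refinement; an approximate Laplace-REML criterion is
available behind `lam="reml"`.  Negative-binomial overdispersion is
profiled by maximum likelihood, alternating with the IRLS updates until the
log-dispersion moves less than 1e-4.  Effective degrees of freedom are
`tr[(XᵀWX+λS)⁻¹XᵀWX]`; the AIC parameter count is the total EDF plus one
for an estimated scale (Gaussian) or dispersion (negative binomial).

Smooth-term p-values are Wald-type on the penalized coefficients with rank
equal to the rounded smooth EDF (F-form for Gaussian, χ² otherwise).  They
are approximate and tend to be anti-conservative, which is why model
selection applies a stricter cutoff (.01) to smooth terms than to
parametric terms (.05).

## Model selection and comparisons

Candidates with 2–5 knots are fit; any candidate whose fitted coefficient
function is not unimodal (more than one sign change in its first
differences over the span range) is rejected.  Among survivors, the fewest
knots not significantly improved upon by a sequential likelihood-ratio test
at .01 wins; the smooth is retained only if it beats the intercept-only
null at .01, and colony intercepts are retained only if they beat a shared
intercept at .05.  LR degrees of freedom use differences of rounded
effective parameter counts; identical fits return p = 1 by convention.

Treatment differences use `ΔAIC = AIC(pooled) − AIC_sep`, with
`AIC_sep = 2Σk_g − 2ΣLL_g` over group-wise fits; a positive value flags a
difference.  For this comparison the model structure is held fixed (full
smooth, colony intercepts) and the group fits inherit the pooled fit's
smoothing parameter: re-selecting structure or smoothness per group adds
noise that flags differences under a truly shared model far too often
(verified by simulation; with the fixed structure the shared-model
positive rate is ~12%, within the accepted ≤25% band).  `k` uses the EDF
convention throughout.

The colony-age screen refits the same machinery with a univariate smooth of
colony age (days since first brood photograph) in place of the functional
term, labels the fitted shape (Constant / Increases / Decreases / Concave /
Convex / Multimodal) from its first differences and extrema, and flags a
vital rate as potentially confounded when the age smooth and the
composition smooth are both significant at .01 — a deliberate
non-identifiability marker rather than an attribution.

Group mean body sizes are compared with a one-way linear model and Tukey
single-step all-pairs contrasts (statsmodels `pairwise_tukeyhsd`).

## Synthetic studies

The generator emulates the study design: three resource treatments (low /
high-low / high) whose worker IT spans are Normal with means 3.16 / 3.31 /
3.68 mm and SD 0.35 mm; 7 colonies per treatment observed over 12 weekly
photo/survey censuses; a worker pool starting at 15, with Poisson(6)
weekly arrivals and 0.75 weekly persistence (workers persist ~3 weeks, so
composition varies enough week to week to identify the smooth).  Egg
counts are NB2 (dispersion 0.2) around 1.4 eggs/day; development time is
overdispersed counts around 14 days floored at 10 (the 8-day exclusion
cap is half of a ~16-day normal development); daily survival is logistic
around 0.99; callow cohort sizes are Normal with SD 0.35 mm; 10% of dying
cells are recorded unseen rather than dead.

Each channel's signal is Σβ(span) over the relevant worker pool, centered
at E[β(X)] under the treatment's span distribution.  Centering is a
vertical shift of β — exactly the component a colony intercept would
absorb — and keeps colony-level rates at their baselines for any effect
magnitude, so effect strength can be varied without destabilizing the
simulated colonies.  The development-time channel applies −β (more helpful
workers shorten development).  The truth record stores the archetype,
magnitude, per-treatment centering, and sign, so recovery scoring compares
the fitted function against the effective linear-predictor truth.

"Strong" effects in recovery experiments are magnitude 1.0 for monotone
archetypes and 2.5 for the unimodal bump (its within-observed-range
amplitude is a fraction of its nominal height, since worker spans
concentrate well inside the bump's support).  A replicate counts as
recovered when the smooth is retained at .01 and the fitted function
correlates with the effective truth at r ≥ 0.7 on a fine span grid —
a shift- and scale-insensitive reading of "same sign pattern".

The `feedback` flag controls colony growth with age: off (default), the
pool is stationary and composition is unconfounded with colony age, making
recovery tests sharp; on, arrival rates grow with week, reproducing the
age–composition collinearity that motivates the confounding screen.
Because callow size responses are measured on the same workers that later
form the composition, the size channel is inherently weakly coupled to the
pool; counts of brood cells and of surveyed workers are otherwise
decoupled, a deliberate simplification.

What passing recovery tests do **not** show: robustness to mis-specified
families, to non-equal-width bins, to irregular census schedules, or to
real-world measurement error in spans and stage calls — the generator
produces none of these.

## Problem sizes and numerical choices

Tests and the acceptance script use the study's design scale (7 colonies ×
12 weeks per treatment; 50 seeded replicates per archetype in recovery
experiments), which completes in minutes on one CPU.  Spans outside a
fitted grid clamp to the end bins; out-of-range evaluation of a
coefficient function is an error.  All randomness flows from explicit
integer seeds through `numpy.random.default_rng`; reruns are
byte-identical.

## Known limitations

* Exact EDF/χ² agreement with other GAM implementations is not a goal; the
  smoothing criterion, basis dimension and p-value conventions are stated
  above and differences of a few percent in EDF are expected.
* The approximate REML criterion is a secondary option and less exercised
  than GCV.
* The binomial day-trial construction attributes an unknown death day to
  the full bracketing interval (no interpolation), as the coding implies.
* Callow cohort statistics treat each survey night's new captures as one
  cohort; with very small cohorts the CV channel is noisy and its rows are
  dropped for singleton cohorts.
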