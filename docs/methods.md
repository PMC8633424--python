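# Methods

## The observer model

`metanoise` simulates a binary categorization task with confidence reports.
Each trial presents a stimulus from one of two categories whose physical
means are separated by μ; the observer receives a percept

    percept ~ Normal(±μ/2, σ_s),

computes the posterior probability of category 1 via Bayes' rule (a
logistic in the percept, `p = 1 / (1 + exp(−μ·percept/σ_s²))`), chooses
category 1 whenever p ≥ 0.5 (ties resolve to category 1; the observer is
unbiased — there is no type 1 criterion parameter), and forms an internal
confidence c = |2p − 1| ∈ [0, 1]. c is choice-independent: p and 1 − p
yield the same c.

Reported confidence is a noisy version of c, drawn from a Beta
distribution parameterized by its mode:

    α = c(1/σ_m − 2) + 1,   β = (1 − c)(1/σ_m − 2) + 1,

so that the mode is exactly c for any spread σ_m ∈ (0, 0.5]. σ_m = 0.5
gives shapes (1, 1) — the uniform distribution, i.e. a metacognitively
blind observer whose reports carry no information; σ_m = 0 is handled as a
deterministic pass-through (the parameterization is undefined there), i.e.
an ideal metacognitive observer. Note σ_m is a spread parameter, not a
standard deviation.

Because only μ/σ_s is identified (it equals the observer's d′), μ is fixed
at 1 everywhere and task difficulty is controlled through σ_s, directly or
through a target accuracy: expected accuracy is Φ(μ/(2σ_s)), inverted by
`sigma_for_accuracy` as σ_s = μ/(2Φ⁻¹(target)). σ_s = 0 is the noiseless
limit (all trials correct, c = 1), which bypasses the logistic.

## Measures

* **d′ / criterion** — equal-variance SDT: d′ = z(H) − z(F),
  c = −(z(H) + z(F))/2, from the choice table collapsed over ratings.
* **AUROC2** — area under the type 2 ROC curve (cumulative type 2 hit rate
  vs false-alarm rate over rating thresholds, trapezoidal), invariant to
  monotone relabeling of ratings and to metacognitive bias.
* **meta-d′** — the type 1 sensitivity an SDT-ideal metacognitive observer
  would need to produce the observed conditional rating distributions.
  Estimated by maximizing the multinomial log-likelihood of the 2×2×K
  counts conditional on (stimulus, response), with the model's type 1
  criterion pinned at the observed relative position c′ = c/d′. The
  2(K−1) type 2 criteria are parameterized as ordered log-increments away
  from meta-c (monotone by construction) and optimized jointly with
  meta-d′ by L-BFGS-B from a data-driven start (criteria at the
  standard-normal quantiles of pooled rating proportions); log-likelihood
  convergence tolerance 1e−6 or better. The fit is undefined at d′ = 0
  and raises.
* **M_diff = meta-d′ − d′**, **M_ratio = meta-d′/d′** (missing at d′ = 0),
  plus regularized M_ratio variants: *exclusion* (missing outside
  [0, 1.6]), *bounding* (clipped to [0, 1.6]; 1.6 is symmetric about a
  typical median of 0.8), *logarithm* (log after flooring at 0.1), and
  *hierarchical* (below). |M_ratio| > 10 is treated as unusable in
  reliability analyses.

### Numerical conventions

* **Cell padding.** 1/(2K) is added to every stimulus×response×rating cell
  before computing rates and likelihoods (the convention of the classic
  meta-d′ code), so z-transforms and log-likelihoods stay finite at small
  counts. Padding is applied consistently to d′ and meta-d′.
* **Discretization.** Continuous confidence is discretized per session
  into K = 6 percentile bins (balanced counts; duplicate quantile edges
  collapsed and ratings renumbered consecutively, so heavily tied scales
  yield fewer levels). K is configurable; 6 is the cap used throughout.
* **Degenerate inputs.** All-identical confidence maps to a single rating;
  AUROC2 is undefined (NaN in pipelines) without both correct and
  incorrect trials; negative integer ratings are floored at 1.

### Hierarchical M_ratio

Subject-level log M_ratio values get a group prior:
log M_ratio_i ~ Normal(μ_g, τ), with weakly-informative hyperpriors
(μ_g ~ N(0, 1), i.e. centered on M_ratio = 1; τ ~ HalfNormal(1)). Each
subject's data enter through the exact type 2 likelihood, profiled over
the type 2 criteria on a 41-point log-M_ratio grid and interpolated with a
cubic spline; the joint posterior is then sampled with the
affine-invariant ensemble sampler (emcee, non-centered parameterization,
800 steps, first 400 discarded). Estimates are posterior means. This
two-stage profile-likelihood construction keeps the sampler dimension at
n_subjects + 2 while preserving the likelihood's shape in the parameter
that the prior acts on. Convergence is reported via the mean acceptance
fraction; NMAE is never computed on hierarchical estimates because the
per-session group priors compress each session around its own mean.

## Reliability

Test-retest agreement uses the Pearson correlation and the normalized
mean absolute error

    NMAE(x, y) = mean|x_i − y_i| / (½·mean|x_i − ȳ| + ½·mean|y_i − x̄|),

which is invariant to common positive affine transforms of both sessions.
Split-half sessions assign odd trial positions (1st, 3rd, …) to "test" and
even positions to "retest". Missing values are removed pairwise per
measure (not listwise across measures) and drop counts are reported.

## Simulation studies

* **Dependency grid** (`run_dependency_grid`): for each (σ_s, σ_m) cell,
  independent subjects are simulated and all measures summarized by mean
  and asymmetric SDs (RMS deviation computed separately below and above
  the mean — the two one-sided spreads of a skewed distribution). The
  desk-scale default uses 10 σ_s levels placed at 1/d′ for d′ targets
  evenly spaced on [0.25, 4] (a linear σ_s grid at 10 points would leave
  the d′ axis nearly empty above 2), 200 subjects and 2000 trials; the
  full design (100 linear σ_s levels in (0, 5], 1000 subjects, 10⁴
  trials) is `DependencyGridSpec.paper_scale()`.
* **Reliability grid** (`run_reliability_grid`): for each (accuracy,
  n_trials) cell and iteration, a 100-subject cohort is drawn with σ_m ~
  U(0, 0.5) per subject — spanning ideal to blind metacognition — *fixed
  across that subject's two sessions* (a stable trait is what makes
  test-retest meaningful; the plausible alternative of redrawing σ_m
  between sessions would make the true reliability zero by construction).
  Pearson r and NMAE are averaged across iterations as plain means (not
  Fisher-z; the arithmetic mean is what the per-cell summaries report).
  Desk-scale default: 20 iterations over a 4×4 lattice;
  `ReliabilityGridSpec.paper_scale()` gives 55–95% accuracy, 25–1000
  trials in steps of 25, 300 iterations.
* **d′-binned curves** (`bin_by_dprime`): overlapping ±0.2 windows
  centered at 0.3–2.9 in steps of 0.2, restricted to d′ ∈ [0.1, 3.1],
  with mean and SEM per window (SEM undefined for singleton windows).

Randomness is governed by a single seed per cohort/grid; per-subject and
per-iteration streams are spawned deterministically from it, so any
subject is reproducible in isolation and identical seeds give identical
tables.

## What the simulations do and do not show

The generator produces exactly the model's assumptions: equiprobable
categories, Gaussian percepts, an unbiased observer with perfect knowledge
of its own sensory noise, stationary parameters within and across
sessions, and Beta-shaped report noise. Real confidence data violate
several of these (type 1 bias, learning and fatigue, post-decisional
evidence, lapses, idiosyncratic scale use), so passing simulation checks
validates the estimators and the qualitative dependence/reliability
patterns under the model — not any claim about a particular empirical
dataset. The `dataio` module's empirical track (Confidence-Database-style
CSVs, 400-trial / d′ > 0.5 inclusion, trial-count binning, cross-validated
split-half d′) prepares real data for the same pipeline but ships no data.

## Known limitations

* No type 1 bias parameter, response-conditional meta-d′,
  unequal-variance SDT, response times, or within-session learning.
* The hierarchical model is fit per cohort; estimates depend on the
  cohort-specific group average and are not comparable across separately
  fitted cohorts.
* Alternative metacognitive noise distributions are supported only insofar
  as `sample_confidence` is a small, replaceable function; only the Beta
  family is built in.
* Verbal-rating and wagering-scale conversions are user-supplied
  configuration, not code.
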