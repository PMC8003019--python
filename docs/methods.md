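# Methods

## Model

Each disseminated tumour cell (DTC) lineage in bone is a linear
(density-independent) birth–death process: a population of N cells gains a
cell at total rate λN and loses one at total rate μN, with constant
per-capita rates λ (proliferation) and μ (death). Time units are arbitrary;
all fate probabilities depend on the rates only through the ratio A = μ/λ,
which the package verifies as an invariance property.

For one founder the extinction probability is the smallest fixed point of
the offspring generating function, q = min(A, 1), and the finite-time
version solves the PGF equation:

    q(t) = μ(e^{(λ−μ)t} − 1) / (λ e^{(λ−μ)t} − μ),   λ ≠ μ
    q(t) = λt / (1 + λt),                              λ = μ.

An animal seeded with n DTCs develops an overt lesion iff at least one
lineage escapes. With a proliferative fraction f (non-proliferative cells
never divide; in the simulator they die at rate μ so every trajectory
absorbs, a choice that cannot affect outgrowth):

    P(tumor) = 1 − ((1 − f) + f·q)^n        (mixture form, default)
    P(tumor) = 1 − q^{f n}                  (exponent form)

The mixture form is the exact result when each founder is independently
proliferative with probability f; the exponent form replaces the random
number of proliferative founders by its expectation f·n. They coincide at
f = 1 and at n = 1 they differ by < 0.1% near A = 0.885, but the gap grows
with n: on A ∈ [0.8, 1), n ≤ 50, f = 0.11 the maximum absolute difference
is ≈ 0.036 (reported by the acceptance script as
`model_variant_max_abs_diff`). Because only the mixture form has an exact
probabilistic derivation it is the default everywhere; the exponent form is
kept for comparison behind the `variant` argument / `--variant` flag.

Assumptions worth stating: rates are constant in time and independent of
niche position, population size and immune state; founders behave
independently. These are deliberate simplifications — the package models
the count process only, not its spatial regulation.

## Simulation

`simulate_birth_death` is a plain event-driven (Gillespie) sampler:
exponential waiting times with rate (λ+μ)N, next event a birth with
probability λ/(λ+μ), run to extinction (N = 0), outgrowth
(N ≥ threshold), an event cap, or an optional time horizon.

`estimate_p_tumor_mc` needs only the absorption outcome, which depends
only on the embedded discrete jump chain. It therefore simulates that
chain with *exact binomial block updates*: from population N with
threshold T, a block of m = min(N, T − N) steps cannot cross either
absorbing boundary except by landing exactly on it, so the net
displacement 2B − m with B ~ Binomial(m, λ/(λ+μ)) is an exact multi-step
transition. This makes the estimator vectorisable over hundreds of
thousands of lineages and fast even near criticality, where per-event
simulation of escaping lineages is prohibitively slow. Lineages still
unabsorbed at the block cap (never observed in practice) are counted as
outgrown only if they have grown well past their founder, and a warning is
logged.

Outgrowth is declared at N ≥ 1000 by default. The threshold is not a
biological quantity — escape of a supercritical process is effectively
permanent long before that — and the test suite checks that raising it
10× moves estimates by less than one standard error for A ≤ 0.9.

Determinism: each sampler takes a `seed` and drives a single
`numpy.random.Generator`, so a fixed (seed, arguments) pair reproduces
results exactly. Replicates are not assigned independent substreams; batch
results are reproducible as a whole rather than per replicate, a trade
made for the vectorised estimator.

`sample_extinction_times` follows 1-founder lineages only to a time
horizon, marking lineages that reach population 1000 as survivors
(their subsequent extinction probability is ~A^1000, far below Monte-Carlo
resolution); its empirical CDF is the stochastic twin of q(t).

## Fitting

Each animal contributes a Bernoulli outcome y (lesion / no lesion) with
success probability P(tumor | n, A, f), giving the log-likelihood
Σ yᵢ ln Pᵢ + (1−yᵢ) ln(1−Pᵢ); outcomes that are impossible under the
parameters make it −∞. The binary per-animal likelihood is the natural
criterion for cohort data where each mouse either develops an overt lesion
or does not.

The MLE over A ∈ [0, 1] is found by a dense grid scan (step 10⁻³, after
collapsing the cohort to unique (n, y) classes so the scan is a small
matrix product) refined by bounded scalar minimisation to 10⁻⁶.
Cohorts in which every informative animal outgrew (Â = 0) or none did
(Â = 1) are returned directly with the `boundary` flag set. Confidence
intervals are percentile nonparametric bootstrap over animals
(default 1000 resamples, drawn as multinomial class weights, which is
equivalent to resampling records and keeps the whole bootstrap a single
matrix product); the interval is widened if necessary to contain the point
estimate, and bootstrap optima are located on the grid (resolution 10⁻³,
well below the sampling noise of desk-scale cohorts).

f is fixed during fitting (1.0 for the all-proliferative model, 0.11 for
the restricted model, the latter taken from prior clonal analyses of the
MDA-MB-231 line rather than estimated). `fit_joint` offers a 2-D grid MLE
over (A, f) but logs a weak-identifiability warning: binary outcomes
constrain only the per-cell no-outgrowth probability (1−f) + f·A, so the
likelihood has a near-flat ridge.

Records with n = 0 are retained (they force outcome 0 and contribute a
constant) and logged.

## Synthetic data

The generator's defaults encode the study conditions rather than
convenient test settings:

- Cohorts: per-animal DTC counts are negative binomial
  (mean 20 outgrowth / 7 indolence — a 65% reduction — dispersion 5).
  Overdispersed counts are the standard choice for per-animal colonization
  numbers; the in vivo counts are reported only graphically, so mean 20 and
  dispersion 5 are documented stand-ins, overridable per `GroupScenario`.
  Outcomes are Bernoulli with the closed-form P(tumor) at the group's true
  (A, f); default true A = 0.885.
- Niche observations: association categories (perivascular-only,
  endosteal-only, overlapping, neither) are multinomial with defaults
  (33.4, 10.0, 56.6, 0)% for outgrowth and (16.1, 18.3, 65.6, 0)% for
  indolence — the single-niche proportions are the reported values and the
  overlapping proportion is their complement, consistent with the reported
  ~50–60% overlapping fraction; "neither" defaults to 0 because the
  reported categories exhaust the observed cells. Contact distances are
  uniform on [0, r] for associated compartments and r + Exponential(20 µm)
  otherwise (r = 10 µm contact radius), so classification recovers the
  sampled category exactly. Growth-plate distances are truncated
  exponential on [0, 200] µm with scale 80 µm (outgrowth) vs 45 µm
  (indolence), making indolent DTCs stochastically closer to the growth
  plate; the scales are tunable plumbing chosen to reproduce the direction
  of the observed shift, not measured values. Among vessel-associated DTCs
  the vessel is type-H with probability 0.7 (outgrowth) vs 0.5 (indolence),
  encoding a type-H bias in young animals and none in mature ones.

What the generator does *not* emulate: spatial correlation between cells
of one animal, measurement error in distances, animal-to-animal
heterogeneity beyond multinomial/negative-binomial sampling noise, and any
dependence of lineage fate on niche position. Passing tests therefore
demonstrate internal consistency of the pipeline (generation →
classification → summary → test, and generation → fitting → recovery) at
the reported effect sizes, not correctness on real histology data.

## Descriptive statistics

"Associated" is operationalized as distance ≤ 10 µm; the criterion is an
analysis choice (the original association calls were made visually on
microscopy), exposed as `contact_radius` everywhere. The animal is the
replication unit: proportions are computed per animal, then averaged;
SEMs and two-sample Student's t-tests (equal-variance, two-tailed by
default) are taken across animals, matching a design with ~5 mice per
condition. Cell-level pooling would understate between-animal variance.
Per-category p-values are reported unadjusted, with a Holm-adjusted column
emitted alongside. A single-animal group yields SEM 0 with a warning;
identical groups yield t = 0, p = 1 rather than NaN.

## Numerical choices

- Probabilities are computed via `log1p`/`expm1` where cancellation
  matters; q(t) clamps to [0, min(A,1)] and switches to the limit when
  (λ−μ)t > 700 to avoid overflow.
- Likelihood grids replace −∞ by a −10¹² floor only inside bootstrap
  matrix products (counts ≤ 10⁶ keep the product finite and dominant);
  user-facing likelihoods keep true −∞.
- Contact radius comparisons are inclusive (≤ r is associated).
- Distance histograms close the last bin on the right so a cell at exactly
  200 µm is counted.
- CSV floats are written at full precision and re-read with
  `float_precision="round_trip"`, so write→read is loss-free; outputs
  carry no timestamps, making seeded runs byte-identical.

## Problem sizes

The test suite and acceptance script use 10⁵ Monte-Carlo replicates per
grid cell, 10⁵ lineages for finite-time checks, 100 synthetic cohorts of
500 animals with 1000 bootstrap resamples each, and 100 five-animal
two-group experiments for the contrast power check; the full acceptance
script completes in well under a minute on one CPU thanks to the block
simulator and the matrix-form bootstrap.

## Known limitations

- The original fitted value Â = 0.885 cannot be re-derived from data: the
  underlying outgrowth outcomes are not published. It enters the package
  only as the generator's default true ratio and the worked-example
  parameter; what the package demonstrates is recovery of a known truth
  from synthetic cohorts of realistic size.
- Near A = 1 the Bernoulli likelihood is flat in A; estimates from small
  cohorts are noisy there, which is the regime of biological interest.
  The bootstrap CI (rather than a Wald interval) is used for exactly this
  reason.
- No calendar time scale: the data constrain only the ratio A, so
  simulated times are in units of 1/λ.
- No covariate regression of A (group-specific fits are obtained by
  filtering the cohort) and no spatial or immune modulation of rates.
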