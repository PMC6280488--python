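# Methods

## Model

Blood-loss volume V (mL, or grams treated as mL-equivalent — the unit
is recorded, never numerically converted) is modelled as a
three-parameter lognormal law

    V = t + exp(m + s·Z),  Z ~ N(0, 1),

with location m (mean of log(V − t)), scale s > 0 (its standard
deviation; natural logarithms throughout — locations of 5.2–5.6 imply
medians exp(m) ≈ 180–280 mL, which only makes sense in natural log),
and threshold t (support shift, mL). t = 0 gives the plain lognormal.
Published fits across large prevention trials put m in ~5.2–5.6, s in
~0.6–0.8, and t between about −50 and +60, with s notably stable
(~0.7); the threshold mostly absorbs measurement-procedure effects
rather than physiology. The physical motivation is multiplicative
accumulation: each increment of loss proportional to the current loss
plus noise pushes log-volume toward normality.

Clinical endpoints are tail events. The lognormal approach estimates
P(V > c) as the fitted survival function at c; since it is a smooth
function of MLEs it is itself an MLE with delta-method uncertainty.
The binomial approach is the raw proportion of volumes ≥ c. Both
target the same quantity; the lognormal route uses the whole sample.

## Fitting

**Two-parameter MLE** is closed form: m̂ and ŝ² are the mean and
(biased, 1/n) variance of log v — jointly sufficient. SEs from the
observed information: se(m̂) = ŝ/√n, se(ŝ) = ŝ/√(2n).

**Three-parameter MLE** uses a profile likelihood: at fixed t the
inner (m, s) maximisation is the closed form applied to v − t, leaving
a one-dimensional search. The likelihood of threshold models is
unbounded as t → min(v), so the fit reports the interior local maximum
with t constrained to min(v) − ε (ε = max(10⁻⁶·|min v|, 10⁻⁹)). The
profile is evaluated on a 160-point grid of gaps g = min(v) − t,
log-spaced from ε up to min(v) + 10·median(v) (equivalently a search
floor of t ≥ −10·median(v); positive thresholds are fully supported —
one published trial has t̂ ≈ +55), then refined by bounded scalar
minimisation in log-gap space between the best grid point's
neighbours. The log-spacing concentrates resolution near the boundary,
where the profile changes fastest; the degenerate boundary spike is
only visible at gaps astronomically smaller than ε for realistic n. A
profile monotone into either end of the grid means the threshold is
not identifiable (common when t ≈ 0 relative to noise); the fit then
falls back to t = 0 with a recorded warning rather than an exception.

SEs and the parameter covariance come from the numerically
differentiated observed information (central differences). The nominal
relative step is 10⁻⁵; because the (m, t) direction is soft, the
smallest eigenvalue is occasionally swamped by floating-point
cancellation at that step, so the step escalates (10⁻⁵ → 10⁻⁴ → 10⁻³)
until the information matrix is positive definite. Samples below n = 10
are rejected for the 3p fit (the threshold is not identifiable in
practice); all-equal samples yield a flagged degenerate result.

**Quantile matching** recovers parameters from published percentiles
(the only option when no participant-level data exist): least-squares
distance between model and reported quantiles, with the 2p case
initialised by regressing log-quantiles on normal scores. With as many
pairs as parameters the fit interpolates. No likelihood-based
uncertainty is attached.

**Model choice** is by AIC with BIC tiebreak (k = 2 vs 3); only the
two lognormal variants are compared.

## Intervals

- Proportions (both approaches) use Wald intervals transported to the
  logit scale and back, keeping them inside (0, 1) — material for
  severe-event probabilities of 1.5–4%. A plain Wald-on-proportion
  variant sits behind a switch. The delta-method variance for the
  fitted tail uses the gradient of the survival function in all free
  parameters, including t, whose uncertainty is far from negligible.
- Binomial relative risk: Katz interval,
  exp(log RR ± 1.96·√(1/x₁ − 1/n₁ + 1/x₂ − 1/n₂)).
- Lognormal relative risk: nonparametric matched-row bootstrap. Each
  arm is resampled with replacement and refitted (3p, falling back to
  2p when a resample degenerates); the b-th replicates of the two arms
  are paired and their tail-probability ratio recorded; the CI is the
  2.5/97.5 percentile of the draws. Replicates with non-finite ratios
  are redrawn, capped at 10% of the bootstrap size (beyond that the
  run aborts with diagnostics). A bias-corrected-and-accelerated
  variant (delete-one jackknife acceleration) is available behind a
  flag; it refits n₁ + n₂ times and suits small samples only.
  Resampling is parametrised by an explicit integer seed; results are
  bit-reproducible given (data, n_boot, seed).

## Event convention

The binomial count uses v ≥ cutoff (the clinical definitions are
inclusive, and heaped data put genuine mass exactly at 500/1000); for
the continuous model P(V > c) = P(V ≥ c). With heaping the choice is
material for counts and is therefore fixed and documented here.

## Sample size

Binomial route (two proportions, normal approximation, no continuity
correction, pooled variance under the null):

    n/group = ⌈(z₁₋α √(2 p̄ q̄) + z_pow √(p₁q₁ + p₂q₂))² / (p₁ − p₂)²⌉.

Lognormal route: each rate p maps to a location m = log(c) − z₁₋ₚ·s
(inverting P(V > c) = p at known s), then the two-means formula
n/group = ⌈2 s² (z₁₋α + z_pow)² / (m₁ − m₂)²⌉. The scale and cutoff
cancel algebraically — n depends on the rates only through their
z-quantile gap — and the module asserts this. For the reference design
(2% vs 1.5%, one-sided 5%, 80% power) full-precision arithmetic gives
914/group (1828 total) against a commonly quoted 916/1832; the
quoted figure's final arithmetic path is not recoverable, so totals in
[1828, 1832] are treated as equivalent. A `paper_rounding` flag
reruns the calculation with 4-dp z-values (913/group); it does not
reproduce 916 either. z-quantiles are otherwise full precision.

## Diagnostics

Digit preference compares observed frequencies of multiples of
10/50/100 against the (0.10, 0.02, 0.01) expected under unheaped
integer recording; non-integer records count as non-multiples. The
limit-of-detection check runs a one-sample Kolmogorov–Smirnov test of
sub-candidate values against Uniform(0, L) (candidates 50 and 100 mL by
default, skipped below 10 sub-candidate observations); "uniformity not
rejected at 5%" flags L as a plausible LOD. The KS test is a documented
choice — sub-LOD uniformity is an empirical observation, not attached
to a named test.

Plot data use Hazen plotting positions (i − 0.5)/n. The
probability-plot band maps beta order-statistic quantiles
(p₍ᵢ₎ ~ Beta(i, n−i+1)) through the fitted quantile function — a
pointwise ~95% band on the data axis. The CDF overlay carries a
delta-method band for the fitted CDF and a pointwise logit-Wald band
for the empirical CDF, matching the estimation conventions. All plot
data are deterministic functions of (sample, fit); rendering is out of
scope.

## Synthetic data

The generator draws threshold-lognormal truth per arm, then applies the
two artefacts in measurement order: hierarchical heaping (with
probability p₁₀₀ round to nearest 100, else p₅₀ to nearest 50, else
p₁₀ to nearest 10, else integer mL), then limit-of-detection smearing
(records whose *true* value lies below the LOD are replaced by
integer-rounded Uniform(0, LOD) noise). Nonpositive final records are
redrawn (configs that mostly produce them are rejected). Ground truth
(parameters, tail probabilities at 500/1000, their ratio for two arms)
is returned for recovery studies.

Heaping calibration inverts the hierarchical mechanism exactly: a
record rounded to the nearest 50 is a multiple of 100 about half the
time, one rounded to nearest 10 a multiple of 50 a fifth of the time,
giving the linear system f₁₀₀ = p₁₀₀ + p₅₀/2 + p₁₀/10 + r/100 (and
analogues), solved by bounded least squares. The strongest observed
column (0.90/0.59/0.42) is exactly representable; the intermediate one
(0.35/0.09/0.03) is not under nesting (its multiple-of-100 excess is
too small relative to its multiple-of-50 excess), and gets the closest
nonnegative solution.

Preloaded scenarios carry published per-arm parameter fits, calibrated
heaping, trial-appropriate LOD (100 mL for the volume-measured trial,
50 for the weighed ones) and approximate arm sizes (9000 for the large
trials, 100 for the small one — the exact published arm sizes are not
restated here). One scenario has positive thresholds (t ≈ +55, +63),
exercising that branch.

**Rejection sampling vs the exact law.** A threshold law with t < 0
puts a small mass (0.3–0.6% at some published parameter sets) on
nonpositive values; redrawing them — necessary for physical data —
samples the law conditioned on V > 0, whose MLE pseudo-truth can sit
many SEs from the generating parameters at n = 20,000. Estimator
recovery studies therefore use `model_volume_draws`, which exploits the
family's exact closure under translation: draws are shifted by
c = max(0, 1 − t) into positivity and the fitted threshold compared
after subtracting c. Tail-probability and RR studies use the rejection
generator; the induced distortion of tail ratios is ~10⁻⁴, negligible
against the Monte-Carlo noise at the sizes used.

## What the synthetic studies do and do not show

Passing recovery/coverage tests show the estimators work when the model
is true and under the modelled artefacts (heaping, uniform sub-LOD
noise). They do not validate the lognormal assumption for any new
dataset — that is what the diagnostics are for — and they say nothing
about tail behaviour beyond ~2000 mL, where the published evidence is
thin and extreme-value techniques would be preferable. Real data
features not emulated: correlated measurement error, caregiver
intervention feedback on the loss process, covariates, and missing
data beyond simple row drops.

## Simulation sizes

Chosen as the package's own test design: parameter recovery at
n = 20,000 per replicate, 100 replicates per parameter set (3-SE
recovery in ≥95% for m and s, ≥90% for the harder t); CI width ratios
at n = 9000/arm, 100 replicates; delta-method coverage at n = 5000,
150 replicates; bootstrap RR coverage at n = 800/arm with 300
bootstrap replicates and 200 outer replicates (92–97% band). Bootstrap
sizes for production use default to 1000.

## Known limitations

- No censored or truncated likelihoods: sub-LOD values are used as
  recorded. The threshold parameter absorbs much of the resulting
  left-tail distortion, which is precisely why the 3p model fits
  heaped/LOD-contaminated data well, but t then mixes measurement and
  physiology and should not be over-interpreted.
- The profile search reports an interior local maximum; for
  pathological samples with several interior optima the global one is
  found only to grid resolution before refinement.
- Delta-method and logit-Wald intervals are asymptotic; for very small
  trials (tens per arm) the bootstrap (or BCa) route is preferable.
- Two-arm designs only; multi-arm trials must be compared pairwise.
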