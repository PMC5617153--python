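# Methods

This note documents the modelling choices in `flightbn`: the statistical
procedures, the defaults and why, what the synthetic generator does and
does not emulate, and the numerical conventions.

## Case files and filtering

The modelling unit is the **site-hour**: counts from the (three) traps at a
site are pooled per hour.  The source study is ambiguous between trap-hours
and site-hours; site-hours match the arithmetic of its sampling effort
(4 sites × 78 days × 24 h ≈ 7,500 hours before fault losses), so pooled
site-hours are the default and trap-level resolution is out of scope.

Signed time covariates follow the convention *negative before the event*:
`t_sunrise_min = hour_start − sunrise` in minutes, likewise for sunset.
This lets evidence statements such as "hours beginning 20 min before
sunset" be expressed directly.

Two filters precede modelling:

- **fault days** — if any hour of a site-day is fault-flagged, the entire
  site-day is excluded (a fault invalidates the whole 24 h rotation of the
  trap carousel);
- **anomaly screening** — positive catches under biologically implausible
  conditions indicate carryover of insects between trap containers, not
  flight: scolytid catches below 5 °C (observed flight otherwise starts
  above ~6 °C) and catches of the strictly nocturnal cerambycid at photon
  flux density above 500 µmol m⁻² s⁻¹.  Flagged catches are zeroed in the
  *modelling view* only; raw counts are retained for reporting.

Missing covariates are preserved at I/O (never imputed); EM handles them
during learning and exact marginal inference handles them at prediction.
Reported percentages round half-up to the printed precision.

## Discretization

*Unsupervised* (for response curves): 20 intervals, equal-width by default.
For wind, where flight concentrates at low speeds, a left-shifted variant
uses geometric bin-width growth with the first bin a quarter of the
equal-width bin — the growth ratio is solved numerically so the bins span
the observed range exactly.

*Supervised* (for the network): recursive binary splitting minimizing class
entropy, with a split on S into S1, S2 accepted iff

    Gain > log2(N−1)/N + Δ/N,
    Δ = log2(3^k − 2) − [k·Ent(S) − k1·Ent(S1) − k2·Ent(S2)],

k being the number of classes present.  Candidate cuts are midpoints
between distinct adjacent sorted values; the optimal cut is always at a
class-boundary point, so only those are evaluated (the test suite checks
equivalence against an exhaustive search without the shortcut).  Ties in
entropy resolve to the leftmost cut.  A variable whose first split is
rejected is *uninformative* and excluded from the network.  Intervals are
half-open [lo, hi) with the last bin closed; out-of-range values clamp to
the end bins.

## Network learning

Structure: TAN.  Conditional mutual information I(Xi; Xj | C) is estimated
from empirical counts with one pseudo-count per joint cell (the study does
not state a smoothing rule; α = 1 keeps sparse cells finite).  The
maximum-weight spanning tree is built by Kruskal with ties broken by
lexicographic edge name, and directed outward from the first feature in
canonical column order — both choices exist only to make structures
deterministic.  A single predictor degrades to naive Bayes with a notice.
Naive Bayes and automatic selection (training classification accuracy at
τ = 0.5) are also available; richer structure searches (general DAG
learning) are out of scope.

Parameters: EM with Dirichlet α = 1, relative log-likelihood tolerance
1e-6, at most 200 iterations.  Complete data needs a single closed-form
iteration, (count + α)/(total + α·n_states); incomplete cases contribute
expected counts under the current posteriors, computed by enumeration over
each case's missing variables (cheap because missingness is sparse and
per-case).  The observed-data log-likelihood is non-decreasing across
iterations and asserted so in tests.  With α = 0 an unobserved parent
configuration falls back to a uniform distribution with a warning.

Inference is exact message passing over the predictor tree conditioned on
each class value (linear in the number of predictors); fully observed
cases are scored by vectorized log-table lookups.

## Evaluation

Scores use the probability assigned to the true state, Pc: logarithmic
loss mean(−ln Pc) (natural log, the convention of the BN tools this
mirrors; base configurable), quadratic (Brier) loss mean(1 − 2Pc + ΣPj²),
spherical payoff mean(Pc/√ΣPj²), AUC by the rank statistic with tie
correction, and Gini = 2·AUC − 1.

Classification uses the *no-flight threshold* τ: predict no flight iff
P(no flight) ≥ τ, ties predicting no flight (tie handling is not specified
by the source; ≥ is the conservative biosecurity reading).  Error
denominators are per-class: Type I = FP/actual negatives, Type II =
FN/actual positives, total = errors/all cases — the only convention
consistent with a degenerate all-negative classifier scoring (0%, 100%,
positive-rate%).  The identity total = (type1·N_neg + type2·N_pos)/N is
asserted at every threshold.  The modified ROC plots the true-negative
prediction rate (100 − Type I) against Type II error over a grid of 1001
thresholds (0 to 1, step 0.001).

Cross-validation: 100 iterations of 4-fold CV, stratified by the flight
flag by default (positives are rare; unstratified folds risk zero-positive
test folds and are available behind a flag with resampling).  Every
training split re-learns discretizations, structure and parameters from
scratch.  Test-fold posteriors are pooled within an iteration before error
curves are computed (per-fold averaging is the plausible alternative;
pooling weights cases equally).  Mean/SD/min/max are taken across
iterations, and the SD-distance diagnostic is (calibration − CV mean)/CV
SD, reported missing where the SD is zero.

## Sensitivity and influence

Sensitivity rows are computed from the fitted model's distributions, not
raw data (matching post-learning sensitivity tools): MI(C; F) in bits under
the model joint, Percent = 100·MI/H(C) — normalizing by class entropy, the
convention that reproduces the published Percent columns from their MI
columns given the class priors — and variance of beliefs
VB = Σ_f P(f)·[P(flight|f) − P(flight)]², defined on the flight-true state.
Rows sort by VB descending.  Influence runs set each state of one predictor
as sole evidence (others at prior), record the flight posterior, and
summarize per predictor as baseline/min/max; tornado bars sort by range
with name tie-breaks.

## Response curves

The fitted response is an *upper bound*: the maximum observed catch per
interval, fitted at interval midpoints (the source does not state the bin
abscissa; midpoints are unbiased for symmetric kernels).  Gaussian fits
use nonlinear least squares with k₀ = max(y), μ₀ = argmax midpoint, σ₀ =
catch-weighted SD, and up to 20 jittered restarts; k, σ are constrained
positive.  The negative exponential is initialized by log-linearization.
Cook's distances use the linearized hat matrix from the Jacobian at the
solution; screening is a single pass (flag D > 1, remove, refit once).
Wherry's adjusted R² is 1 − (1 − R²)(n − 1)/(n − p − 1); the formula has
variants and the n − p − 1 denominator is used throughout.  The gamma GAM
(inverse link, B-spline smooths) delegates to statsmodels; zero responses
are lifted by the smallest positive response × 10⁻³ before fitting, and
significance against the intercept-only gamma GLM uses the
dispersion-adjusted deviance difference referred to an F distribution
(appropriate when the gamma dispersion is estimated; a naive χ² LRT on
per-model likelihoods is anti-conservative).

## Synthetic generator

The generator reproduces the study design: three non-overlapping sampling
windows (spring and two summer deployments totalling 78 days) at four
sites, hourly resolution.  Defaults:

- **solar model** — declination/hour-angle formula with refraction
  (zenith 90.833°), accurate to a few minutes at the study latitude
  (−43.5°); sufficient because only minutes-since-event covariates matter.
  Polar latitudes are rejected.
- **weather** — seasonal mean temperature (13 °C base, 4.5 °C seasonal
  amplitude peaking at day 20) plus a diel cosine anchored at sunrise
  (minimum) and ~90 min after solar noon (maximum), AR(1) hourly noise and
  site offsets.  Wind (mean 3 m s⁻¹) and relative humidity (mean 68%) are
  drawn conditionally on the standardized realized temperature with
  couplings +0.27 and −0.66 — the correlations reported for the field
  data — so the sample correlations hit those targets for any window.
  PAR follows a clear-sky half-sine scaled by cloud (rain-linked) and is
  exactly zero for hours fully outside daylight; rainfall is
  Bernoulli-exponential.
- **flight** — intensity λ = scale · Gaussian(T; μ, σ) · diel(t) ·
  windmod(w) · seasonal(window), counts Poisson(λ).  The temperature
  kernels use the published species parameters.  Diel kernels: two
  Gaussian bumps (90 min after sunrise, 30 min before sunset) for the
  crepuscular scolytids; one bump 60 min after sunset (σ 35 min), gated to
  zero before sunset and above 500 µmol m⁻² s⁻¹ PAR, for the nocturnal
  cerambycid.  Wind modifiers: a gamma-shaped hump peaking at 2 m s⁻¹
  (*H. ligniperda*), exp(w/−3.65) (*A. ferus*), flat (*H. ater*).
  Seasonal weights bias *H. ligniperda* to spring, *H. ater* and
  *A. ferus* to late summer.  The count law is Poisson because only
  presence/absence feeds the classifier; no count distribution is
  specified by the source.  Rainfall and temperature range are null
  effects on flight by default (no published effect sizes).
- **calibration** — the per-species `scale` values (1.694, 0.176, 3.470)
  were fixed once by bisection on a fixed-seed pilot run to hit
  positive-hour rates of 11%, 2% and 3%, and are not revisited.
- **imperfections** — trap-fault days at rate 0.045 per site-day (chosen
  so the retained hours land near the study's ~7,100) and
  container-carryover anomalies (positive catches injected into
  implausible hours) at small per-species rates.

What the generator does **not** emulate: spatial structure among traps,
weather fronts and multi-day synoptic persistence, trap-sensitivity
differences between species and lures, density dependence, and
between-year phenology shifts.  Passing tests therefore demonstrate that
the pipeline recovers structure it is designed to detect under the study's
sampling conditions — not that the fitted error rates transfer to real
trap data.

## Problem sizes in tests

The unit suites run on reduced replicas of the analysis (two-site
fortnight case files, 2–10 CV iterations, 20–60 seeded replicates for
stochastic properties); the full study-scale generator (~7,500 hours) is
exercised for the case-count, rate, correlation and diel-pattern checks.
These sizes were chosen so the complete suite documents the method's
behaviour at meaningful scale while remaining quick to run.

## Known limitations

- The exhaustive MDL and spanning-tree oracles bound correctness only at
  small n / few features; larger instances rely on the algorithmic
  argument (boundary-point optimality, Kruskal).
- EM's E-step enumerates each case's missing-variable configurations and
  would slow down for cases missing many covariates simultaneously.
- GAM effective degrees of freedom are reported from the unpenalized
  spline basis dimension; per-smooth-term F statistics are not decomposed.
- The classifier calibrates to the synthetic generator's positive-hour
  rates; absolute error rates on real trap data depend on trap
  sensitivity, which is outside the model.
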