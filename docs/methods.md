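# Methods

## GR values

The package quantifies drug response on a per-division basis. With k(c) the
exponential growth rate (doublings per unit time) of cells under
concentration c and k(0) that of vehicle-treated controls,

    GR(c) = 2^(k(c)/k(0)) − 1.

Two endpoint estimators are implemented (`grdose.gr`):

* **Fixed difference** (Case A): requires a time-zero count x₀ and endpoint
  control/treated counts x(0), x(c); the rate ratio is
  log2(x(c)/x₀) / log2(x(0)/x₀).
* **Division time** (Case C): requires the endpoint treated/control ratio,
  the assay duration T and the untreated doubling time T_d; the exponent is
  (log2(x(c)/x(0)) + T/T_d)/(T/T_d).

The two agree exactly whenever the control actually grew 2^(T/T_d)-fold
(enforced as a property test). A non-growing control (x(0) ≤ x₀, or
k(0) ≤ 0) is a hard domain error rather than a silent NaN: the method
presumes proliferating controls, and surfacing the violation beats emitting
nonsense metrics. GR values above 1 (growth stimulation) are legal and
never clipped.

## Condition definition and replicate averaging

Each unique combination of the selected grouping-variable values defines an
experimental condition; non-grouping metadata (typically replicates) are
averaged *after* GR/relative-count computation, per concentration, by
arithmetic mean. Averaging normalized values rather than raw counts makes
the collapse robust to plating differences between replicates. Duplicate
concentrations within a replicate are treated as extra replicates.
`concentration` can never be a grouping key. By default every metadata
column is a grouping key (no averaging).

## Curve model and fitting

Both response scales are fitted to a 3-parameter logistic with the upper
asymptote pinned at 1 — the untreated condition defines y = 1 by
construction of GR and of relative count:

    y(c) = y_inf + (1 − y_inf) / (1 + (c/c50)^h)

Fitting (`grdose.fitting.fit_logistic`) is bounded nonlinear least squares
(scipy `least_squares`, trust-region reflective, analytic Jacobian) in
log10 concentration. Bounds: h ∈ [0.1, 5]; c50 within the tested range
extended 100-fold both ways; y_inf ∈ [−1, 1] for GR and [0, 1] for relative
count. Initialization is a deterministic multi-start grid — c50 at every
tested concentration × h ∈ {1, 2}, y_inf at the smallest observed
response — keeping the lowest residual sum of squares, so identical inputs
always give identical fits without any random restarts. Iterations are
capped at 60 function evaluations per start; a start that hits the cap is
still a usable candidate (the grid is dense enough that the best candidate
is at the global optimum — verified against a 13 × 5 start grid).

### Significance test and flat fallback

The sigmoid is kept only if it beats the flat (mean) model in a
nested-model F-test:

    F = ((RSS_flat − RSS_sig)/2) / (RSS_sig/(n − 3)),   p = SF_{F(2, n−3)}(F)

at significance level α = 0.05 (configurable). The flat fallback also
triggers on optimizer failure or fewer than 4 distinct concentrations.
Under a flat fit the reported metrics are: GR_inf (or E_inf) = mean
response; GEC50, h = NA; GR50 = +Inf when the mean is above 0.5 (no potency
observed anywhere in the tested range — the +Inf convention survives
ranking and capping), and NA when the mean is at or below 0.5 (the crossing
lies below the tested range and is unidentifiable).

**Calibration caveat.** Because the upper asymptote is pinned at 1, the
logistic family has less local freedom around a flat truth than the
F(2, n−3) reference assumes — e.g. flat-truth noise trending upward can
never be chased by a curve forced through 1 at c = 0. The test is therefore
*conservative*: on simulated flat-truth conditions the false-sigmoid rate
at α = 0.05 is ≈ 0.01–0.02 rather than 0.05, at any flat level and with
either Gaussian response noise or the package's own count noise. This errs
in the safe direction for the test's purpose (keeping unreliable sigmoid
extrapolations out of metric tables) but means α is an upper bound on the
type-I rate, not its value.

### Derived metrics

* **GR50 / IC50** — the fitted curve's 0.5-crossing, in closed form:
  c50 · ((1 − y_inf)/(0.5 − y_inf) − 1)^(1/h); +Inf when y_inf ≥ 0.5.
  Optionally capped at a configurable concentration (e.g. the highest
  tested dose), with +Inf mapping to the cap; capping is off by default.
* **GRmax / Emax** — the lowest *measured* (replicate-averaged) response at
  the two highest tested concentrations.
* **GR_AOC / AUC** — trapezoidal integral of (1 − GR), respectively of the
  relative count, over log10 concentration, computed from the measured
  points (not the fitted curve) and divided by the tested log10 range.
  Range normalization makes datasets with different tested ranges
  comparable and the metric dimensionless (0 = inert, 1 = full cytostasis
  for GR_AOC); it also makes the metric invariant to rescaling all
  concentrations, and it can be disabled (`aoc_normalization: none`).
* **Response class** — GR_inf within ±0.05 of zero → cytostatic; above →
  partially cytostatic; below → cytotoxic. The 0.05 tolerance absorbs fit
  noise around exact cytostasis.

GEC50 is reported on the linear concentration scale with a log10 companion
column, since conventions differ between tools.

## Growth model and simulator

The exploration/simulation model (`grdose.simulate`) treats drug effect as
multiplicative Hill inhibition of the growth rate:

    k(c) = (1/T_d) · (1 − SCmax · c^h / (SC50^h + c^h)),
    x(c, t) = x₀ · 2^(k(c)·t)

This is the minimal form in which SC50 is the half-effect concentration,
SCmax = 1 stops growth exactly (cytostatic), SCmax < 1 only slows it, and
SCmax > 1 drives net death. It makes the division-rate confound exact and
inspectable: the model GR curve 2^(1 − SCmax·E(c)) − 1 contains no T_d,
while the relative-count curve 2^((k(c) − k(0))·T) and hence IC50/Emax/AUC
shift with T_d and T. Presets: cytostatic (SCmax = 1), partial_cytostatic
(SCmax = 0.5), cytotoxic (SCmax = 2), sharing T_d = 1 d, T = 3 d,
SC50 = 0.1, h = 2, x₀ = 1000 — chosen as a typical 3-day assay with a
mid-titration potency; the preset SCmax values are the package's own
defaults, fixed so the three response classes are realized exactly.

The dataset generator emulates a factorial screen (cell lines × agents ×
9-point log-spaced titration × replicates) with multiplicative lognormal
count noise (mean-1 factors; CV 0.05 by default when noise is requested,
typical of imaging-based counting). Each (line, agent, replicate) stratum
shares one noisy control and one noisy time-zero well, mimicking a plate
layout; treated wells get independent noise. What it does **not** emulate:
edge effects, pipetting gradients, density-dependent (non-exponential)
growth, delayed drug action, or count-dependent (Poisson-like) noise — so a
green recovery test establishes correctness of the estimators and fitter
under the stated exponential-growth world, not robustness to those
artifacts. With noise CV = 0 the pipeline reproduces the analytic model
curves to machine precision (tested).

## Group comparison

`rank_sum_test` is the two-sided Wilcoxon rank-sum (Mann–Whitney) test via
scipy: exact null distribution when both groups have ≤ 20 values and the
pooled sample is tie-free, otherwise the normal approximation with tie
correction (no continuity correction). +Inf metric values (capped-out or
never-crossing GR50/IC50) are kept and rank largest — dropping them would
bias comparisons toward sensitivity; NA values are dropped with a logged
count. Boxplot summaries use the Tukey convention (whiskers at the most
extreme point within 1.5 × IQR); a p-value is attached only when exactly
two non-empty groups are shown.

## Determinism

Every stochastic step (dataset generation) is driven by an explicit seed;
fitting is seed-free by construction (deterministic start grid). The same
inputs and seed produce byte-identical output tables, which the test suite
checks by hashing.

## Known limitations

* Endpoint estimators only: no growth-rate regression from time-lapse
  trajectories.
* One curve family: no 4/5-parameter logistic, biphasic, or bell-shaped
  models, and no confidence intervals on fitted parameters.
* Case A control/time-zero matching is row-wise; plate-map-aware matching
  must happen upstream.
* The F-test's conservatism (above) means borderline-significant shallow
  responses are somewhat more likely to be reported flat than the nominal
  α suggests.
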