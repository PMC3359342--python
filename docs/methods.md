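# Methods

## The measurement model

A *Pecten maximus* shell records one stria per day; the distance between
consecutive striae (µm) is that day's shell extension along the axis of
maximum growth. Growth halts in winter, so a lifetime series decomposes into
annual growing seasons separated by gaps, and the visible winter rings allow
back-calculation of height-at-age. The package treats a raw series as a
non-negative vector of daily increments with optional calendar-day
annotations; all downstream quantities derive from it.

**Age-class convention.** The age class of a stria is 1 + the number of
winters (1st-of-January crossings) the individual has experienced; the first
growing season is age class 1. Output files record this convention.

## Winter detection and truncation

The source measurements do not label winters; they must be recognized in the
increment series. A winter is declared at every maximal run of at least
`min_stop_run_days` (default 5) consecutive increments at or below
`stop_threshold_um` (default 5 µm d⁻¹). The run length makes the rule robust
to isolated slow days inside a season; the threshold accommodates measurement
floors in real data where a "stop" may digitize as a near-zero rather than
exact-zero width. Truncation removes exactly the flagged runs, re-indexes
each season from growth day 1, and is idempotent: pre-existing break
positions are mapped through the truncation rather than discarded.

Back-calculated height at winter *i* is the umbo offset plus the cumulative
increment sum up to that winter, converted µm → mm. The shell-edge height
always equals the initial offset plus the total increment sum, independent of
break placement (a conservation property the tests enforce).

## Synchronization

Individuals within a cohort start their seasons on different calendar days,
so per-age-class series must be aligned before averaging. The objective is
the sum over unordered pairs of the mean squared difference over overlapping
growth-day indices (normalized by overlap length so long overlaps are not
penalized). Squared rather than absolute differences were chosen for scale
comparability and a smoother landscape.

The optimizer is exhaustive integer-lag search per individual within
±`max_lag_days` (default 30) inside coordinate descent, first individual
pinned at offset 0, ties broken toward the smaller |offset|, at most 50
sweeps. Pairwise costs for all relative lags are precomputed once via the
cross-correlation identity Σ(a−b)² = Σa² + Σb² − 2Σab, which makes the
search O(pairs · series length²) up front and cheap per sweep. Because
per-individual moves cannot translate a mutually aligned block relative to
the pinned anchor, a rigid group-translation move (a common shift of all
non-anchor offsets, scanned exhaustively) runs whenever a sweep reaches a
fixed point; it never increases the objective. The procedure remains a
heuristic — the global optimum is not guaranteed — but on generator cohorts
with known jitters it recovers planted lags within ±1 day essentially always
at 5% daily noise.

Each growth day of the aligned cohort with n ≥ 2 contributors gets a mean
and a 95% CI half-width t(0.975, n−1)·SE; single-contributor days carry the
lone value with half-width 0 and are degenerate by construction (n = 1 in
the output).

Whether one offset should apply per individual across all years or one per
age class is not determined by the problem; the pipeline synchronizes each
age class independently, matching the year-by-year framing of the objective.

## Season metrics

* **MDG** (µm d⁻¹): the maximum over all contiguous 10-increment windows of
  the window mean, with the SE of the argmax window's values; the
  first-occurring window wins ties. Computed on the synchronized mean
  trajectory at population level (a per-individual variant is available).
* **Growth days per age**: stria counts strictly between consecutive winter
  breaks. At station level these come from per-individual counts, not from
  the aligned trajectory's span — the union of jittered series overstates
  season length by the jitter spread.
* **MNG**: the maximum of growth days over age classes.
* **Ω** (d yr⁻¹): the OLS slope of growth days on age class, pooling all
  (individual, age) points, with SE and R². Northern populations peak in
  their second or third season, so the regression can optionally start at
  the MNG age class (`omega_from_mng_age`); the choice is recorded in the
  output. The default fits all age classes.

Note one subtlety: MDG is bounded above by the largest single increment but
is *not* always bounded below by the overall series mean — the bound holds
when the 10-day windows tile the series, and the property tests respect
that restriction.

## Von Bertalanffy growth and Φ′

Height-at-age pairs (pooled over a station's individuals) are fitted to
H(t) = H∞·(1 − e^(−k(t − t0))) by Levenberg–Marquardt least squares.
The negative exponent is required for the curve to saturate and is the form
all tabulated parameter sets are consistent with. Starting values are
H∞ = 1.1·max(height), k = 0.3 yr⁻¹, t0 = 0, with up to 5 deterministically
jittered restarts on non-convergence, so a fit is reproducible for given
data. 95% CIs are asymptotic (Wald), Student-t on n − 3 residual df;
R² = 1 − SSR/SST. At least 4 distinct ages are required. Two degeneracies
raise an explicit error rather than returning a confident artefact: an
inestimable covariance, and a fitted curve already saturated before the
first observed age (constant heights fit such a curve perfectly while k is
unidentified).

Φ′ = log₁₀(k) + 2·log₁₀(0.1·H∞), k in yr⁻¹ and H∞ in mm — base-10
logarithms, verified against the packaged growth table (recomputed Φ′
matches the tabulated column at 2 dp for all 12 stations). Values are kept
unrounded internally and rounded only for reporting.

## Comparative statistics

Simple regression reports slope/intercept with SEs, R², F = MSR/MSE with
dfm = 1 and dfe = n − 2, the upper-tail p, and both internally and
externally (leave-one-out deleted) studentized residuals (statsmodels OLS
underneath). When the data lie on an exact line, studentized residuals are
reported as true zeros instead of ratios of float noise.

The Arrhenius model regresses ln Φ′ on 1/(T + 273.15). In the packaged
comparison chlorophyll *a* enters its latitude regression log-transformed
(its station distribution is right-skewed); temperature enters raw.

Outlier detection compares |studentized residual| to the two-sided t
critical value at level α (default 0.05). The externally studentized
(deleted) residual is the default test statistic; the comparison df defaults
to n − 2 (the convention used in the source reports) although the textbook
external-residual df is n − 3 — both variants are always computed and the
df is configurable, so the choice is visible rather than silent.

The Chow test compares one pooled line against two segment-wise lines:
F = [(SSRp − SSR1 − SSR2)/2] / [(SSR1 + SSR2)/(n − 4)] with p from
F(2, n − 4); each segment needs ≥ 3 points and all three SSRs are returned
for audit. A scan helper reports the best split when the breakpoint is not
fixed a priori. One-way ANOVA uses the classical between/within
decomposition with dfm = g − 1, dfe = N − g.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, so
that every stage can be tested against bookkept ground truth. It is not a
mechanistic model: season lengths and peak growth are imposed, not emergent
from temperature or energetics.

For each age class the deterministic daily-growth curve is a cosine-tapered
rise and fall around a plateau occupying the middle 50% of the season
support, multiplied by a shared day-to-day forcing — Gaussian-kernel-smoothed
white noise (correlation length 2 d, sd = 2·noise_cv by default) locked to
the station calendar and identical across individuals, mimicking the common
food/temperature fluctuations that drive day-scale covariation in real
cohorts. Without such shared structure, integer-lag alignment of a smooth
seasonal curve is under-determined to about ±2 days at 5% noise; with it,
synchronization is a well-posed inference problem, which is also why the
procedure works on real shells. The curve is rescaled so its maximum 10-day
running mean equals the configured peak exactly; a noiseless scenario
therefore reproduces the target MDG to machine precision.

Each individual draws from a seeded substream of the scenario seed:
a start jitter (integer, uniform in ±`start_jitter_days`, shifting its
sampling window within the shared calendar), a realized season length
round(nominal · lognormal with CV = `noise_cv`), and independent
multiplicative lognormal daily noise of the same CV (increments are positive
and their variance grows with the mean, which a lognormal captures).
Winters are explicit zero runs sized to keep consecutive season starts 365
days apart; a short trailing winter closes the final season so the last ring
exists. The defaults — 5% noise CV, ±10 d start jitter, seasons of roughly
200–280 days with peaks of 200–270 µm d⁻¹ — reflect the observed range of
daily-growth series along the Northeast-Atlantic gradient; the noise CV is a
free choice, as no distributional information on inter-individual daily
variance is available.

Annual height-at-age tables for growth-curve testing are generated directly
from a von Bertalanffy curve plus Gaussian noise truncated at zero.

What the generator does *not* emulate: measurement error in stria
identification (missed or doubled striae), individual heterogeneity in peak
growth, partial first seasons from mid-year settlement, or any feedback of
temperature on growth. Passing tests therefore demonstrate that the
processing chain recovers the quantities it defines under the stated noise
structure — not that the chain is robust to every pathology of real imagery.

## Problem sizes and numerical choices

Recovery checks run at the scale that makes their sampling error small
relative to the tolerance being asserted: 100 replicate fits of 50-shell
cohorts for the growth-curve interval check, 100 8-shell stations for the Ω
recovery check, 10-shell cohorts for lag recovery, 500-day series for the
exhaustive MDG oracle. Exact-line inputs are treated as exact (SSR below
1e−20 of SST short-circuits studentization and the Chow numerator), ties in
window and lag searches resolve to the first occurrence and the smaller
|offset| respectively, and all fixture statistics are deterministic — reruns
are bit-identical.

## Known limitations

* The synchronization heuristic optimizes a non-convex objective; pathological
  cohorts (e.g. near-periodic forcing) could alias to a wrong lag.
* Pooled-points growth fitting ignores within-individual correlation, so the
  asymptotic CIs understate uncertainty when individuals contribute several
  ages each; a mixed-effects treatment is out of scope.
* The Ω regression treats realized growth days as homoscedastic across ages.
* The Arrhenius α is a descriptive slope; no mechanistic activation energy is
  claimed.
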