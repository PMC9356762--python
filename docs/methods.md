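# Methods

## The estimation problem

Given a gapless Monday-start weekly series of death counts for one
stratum (cause group × place of death × region), the task is to decide,
week by week, whether the observed count is compatible with what past
years predict, and if not, by how much it exceeds (excess) or falls
short of (exiguous) that prediction.  The package answers this with a
modified Farrington procedure: a per-target-week quasi-Poisson
regression on historical counts, a two-sided prediction interval on a
variance-stabilising power scale, and range-style quantification of the
departure.

## Baseline model

For target week *t*, the fit uses the `b·52` weeks immediately
preceding *t* (default `b = 5`).  The mean model is

    log E[Y_s] = α + β s + γ' f(s),   s in the lookback window,

with the trend covariate centred on the target (`s = 0` at *t*), so the
target-week prediction is `μ̂₀ = exp(α̂)` and its estimation variance is
`μ̂₀² · Var[α̂]` — this also keeps the design well conditioned and makes
estimates invariant to the origin of the weekly axis.

`f(s)` is a categorical seasonal factor built from each week's circular
offset `δ = (s − t) mod 52`: offsets within ±`w` of 0 (default `w = 3`,
7 offsets) form the *reference* level, which is the factor's baseline
category and the level at which the target week is predicted; the
remaining 45 offsets, traversed from `w+1` upward, are split into 9
consecutive blocks of 5 (equal lengths, earlier blocks absorbing any
remainder for other `w`/period choices).  Week-53 positions fold into
week 52's level via the mod-52 offset.  With `baseline_mode =
WINDOW_ONLY` the fit instead uses only the reference-window weeks of
the `b` prior years and drops the seasonal terms — the original
subset-style Farrington baseline, retained for comparison; the default
`FULL_HISTORY` mode is required for the seasonal factor to be
estimable at all, since all of its off-season levels are empty in the
window-only subset.

Counts are quasi-Poisson: the coefficients maximise a weighted Poisson
likelihood (IRLS, relative coefficient change < 1e-9, ≤ 100
iterations; singular systems fall back to least squares and empty
seasonal levels drop their dummy with a warning), and the dispersion is
the weighted Pearson statistic over residual degrees of freedom,
floored at 1.  The floor prevents anti-conservative intervals when a
short history happens to be underdispersed.  The coefficient covariance
is `φ̂ (X'WX)⁻¹`.

### Trend handling

The original algorithm drops the linear trend unless it is significant
at 5%, at least 3 years of history are available, and the predicted
value does not exceed every historical observation.  The default here
(`trend_mode = ALWAYS`) retains the trend unconditionally — appropriate
for national-scale mortality where the secular trend is real and
dropping it biases the baseline; `ORIGINAL_CONDITIONAL` implements the
full original rule for comparison.

### Downweighting past aberrations

After an initial unit-weight fit, Anscombe residuals

    r_i = 1.5 (y_i^{2/3} − μ̂_i^{2/3}) / (φ̂^{1/2} μ̂_i^{1/6} (1 − h_i)^{1/2})

are computed (`h_i` the weighted-fit leverage).  Rows with `r_i > 2.58`
receive raw weight `r_i⁻²`, others 1; weights are rescaled to sum to
*n* and the model is refit once (`max_reweight_iter` controls
repeats).  This keeps a past epidemic week from inflating the baseline.
The cutoff is one-sided by construction — only upward aberrations are
downweighted — which makes the refit baseline slightly conservative
downward; the calibration study below quantifies the effect.

### Prediction interval

On the 2/3-power scale (the skewness-symmetrising power for Poisson-type
counts),

    U/L = μ̂₀ (1 ± z · (2/3) · √(φ̂ μ̂₀ + Var[μ̂₀]) / μ̂₀)^{3/2},

with `z = 1.959964` for the default two-sided 95% level and the lower
bound's inner factor floored at 0.  With `φ = 1` and no estimation
variance this tracks the exact Poisson quantile to within one count
over μ̂₀ from 10 to 1000 (verified against pmf summation in the tests).

## Excess/exiguous quantification

A week is flagged EXCESS iff `observed > U`, EXIGUOUS iff
`observed < L` (strict inequalities; a count exactly on a bound is
unflagged).  Weekly excess is the range
`[max(0, observed − U), max(0, observed − expected)]`, exiguous its
mirror image; percentages divide by the expected count, and reported
tables round deaths and percentages to 2 decimals.  Cumulative
summaries sum the endpoints week-wise; by default *every* week
contributes its clipped distances (so an unflagged period can
accumulate a `0–x` high endpoint), with a `flagged_only` switch
restricting contributions to flagged weeks.  Maximal runs of
consecutive EXCESS weeks are reported by the first week's Monday and
the last week's Sunday.

## Reporting-delay adjustment

Provisional trailing weeks are corrected with a multiplicative
completeness nowcast: from a reporting triangle (counts by event week ×
delay 0..D, default D = 13 weeks ≈ three provisional months), pooled
completeness `ĉ_d` = (cumulative reports at delay d over fully observed
weeks) / (final counts) — nondecreasing with `ĉ_D = 1` — and each week
at current delay `d < D` is inflated to `round(count / ĉ_d)`, never
below the observed count.  This is a deliberately simple stand-in for a
full nowcasting model: it ignores day-of-week and holiday effects,
temporal drift in the delay law, and does not propagate nowcast
uncertainty into the prediction interval.  It is bypassable
(`--no-delay-adjustment`).

## Synthetic data

The generator draws weekly counts from

    Y_t ~ NegBin(mean = m_t · exp(α + β t + A sin(2π t / 52.1775 + ψ)), size = k)

with `m_t` the product of episode multipliers covering week *t*
(`k = None` gives the Poisson limit).  Design choices:

- **Annual period 52.1775 weeks** (365.25/7) for the sinusoid, while
  the fitting side uses a categorical mod-52 factor — a deliberate
  mismatch so that passing tests demonstrate robustness to imperfect
  seasonal specification, not a self-fulfilling model match.
- **Negative binomial** realises quasi-Poisson-style overdispersion
  (local dispersion `φ ≈ 1 + μ/k`).
- Record-level output distributes each week's count uniformly over its
  seven days, with ICD-10 codes drawn from a per-category pool, so
  re-aggregation reproduces the weekly counts exactly; delay thinning
  assigns each death an independent delay from a specified law and
  returns the true reporting triangle.

What the generator does *not* emulate: age/sex structure, population
denominators, calendar effects (holidays, registration backlogs),
spatial correlation between regions, and drifting delay laws.  Tests
passing on this generator therefore demonstrate correctness of the
estimation machinery under its stated assumptions, not performance on
real vital-statistics data.

## Validation studies and problem sizes

- **Interval calibration** (`scripts/acceptance.py`, also in the test
  suite): 500 null series — mean ≈ 1000/week (`α = log 1000`,
  `β = 5·10⁻⁴`/week, `A = 0.1`), size `k = 50` (dispersion ≈ 21),
  6 years of history + 52 evaluation weeks — scored week by week with
  the full chain.  Coverage lands near 93.5–93.7%: about 0.7
  percentage points below 95% from the one-sided downweighting and a
  further ~0.8 from the seasonal-form mismatch, both intrinsic to the
  procedure as specified.  Per-seed replicates are driven by
  `numpy.random.SeedSequence(seed)` child states, so a single integer
  seed reproduces the whole study.
- **Episode recovery**: 200 replicates of a 4-week episode at
  multiplier 1.15 on a 5000/week series with `k = 5000` (dispersion
  ≈ 2, typical of a large national cause stratum).  The pipeline flags
  ≥ 3 of the 4 episode weeks in well over 90% of replicates, and at
  multiplier 1.0 flags ≤ 1 week in over 90%.
- **Optimizer equivalence**: on 20 random designs (n = 60–260) the
  IRLS solution matches a generic trust-region maximisation of the
  identical weighted Poisson likelihood (preconditioned to unit column
  norms) to better than 1e-6 both in vector-norm relative error and in
  absolute per-coefficient difference.
- **Round trips**: record-level simulation → aggregation conserves
  counts exactly (place-specific series sum to the all-places series);
  thinning by a front-loaded delay law (70% reported within the event
  week — typical of death registration) → completeness estimation →
  adjustment recovers weekly totals within 5% at ≥ 1000 deaths/week.

These sizes keep the full suite and the acceptance script each within a
few minutes on a single CPU while leaving Monte-Carlo error well inside
the asserted tolerances.

## Known limitations

- The delay adjustment is a stand-in, not a validated nowcast.
- No multiplicity adjustment across the strata grid: each series is
  flagged independently at the 95% level, so ~2.5% of null weeks per
  stratum will be flagged excess by construction.
- Baselines for pandemic-era targets include immediately preceding
  pandemic-era weeks in their history; anomalous recent years therefore
  influence (and in long anomalies, dampen) subsequent estimates.
- Very sparse series (regional × cause strata with few deaths/week) can
  produce empty seasonal levels or non-convergent fits; these are
  logged and surfaced per stratum in the run manifest rather than
  aborting the grid.
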