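# Methods

`lipidrhythm` analyses sparse, self-collected blood-lipid timeseries —
total cholesterol (TC), HDL-cholesterol (HDL) and triglycerides (TG), all
in mg/dL — for three things: whether a person's short-timescale
variability carries them across clinical risk categories, whether that
variability is structured as a daily rhythm, and whether the
point-of-care device producing the data is precise and accurate enough
for the question to be meaningful. A seedable synthetic cohort generator
with the same multi-timescale structure makes every stage testable
end-to-end without any external data.

## Data model and conventions

The atomic record is one timestamped measurement of one analyte with a
fasting flag and optional context (hunger ordinal 0–3, menstrual cycle
day, duplicate-test pair id, clinical reference value). Values outside
(0, 2000) mg/dL are rejected at ingest. Timestamps are naive local clock
times at minute resolution: every analysis is phrased in local time of
day, so no timezone arithmetic exists anywhere. Clock windows are
half-open `[start, end)` to avoid double-counting shared boundaries. A
sample at exactly midnight is treated as hour 24 of the *previous* day,
so a 06:00/12:00/18:00/24:00 serial schedule forms one within-day slice.

A *fasted morning* sample is one flagged as taken after a ≥12 h
water-only fast, inside a clock window that must end by 12:00 (default
06:00–08:00). When a morning holds several qualifying samples of one
analyte, the earliest is kept — the source data never documents which of
several duplicates is canonical, and "earliest" is reproducible.

## Risk categories and crossing statistics

Risk bands are configurable per analyte; the default is the standard US
cholesterol-education banding (TC 200/240; HDL 40/60; TG 150/200/500
mg/dL) with the lower boundary inclusive, matching the conventional
"<200 vs 200–240" phrasing. *Crossing* means one person's grouped
samples fall into ≥2 distinct bands of one analyte.

Two groupings are computed. `within_day` evaluates each calendar day
with ≥2 samples separately; a participant's reported record is the
qualifying day with the largest range, so `crossed` is true exactly when
some *single* day spans two bands (never an artifact of day-to-day
drift). `across_mornings` pools one fasted value per morning across
days. Participants with <2 qualifying samples are excluded from
denominators and logged. Cohort summaries report percent crossing per
analyte and for analyte unions, plus the median and SD (ddof = 1) of
per-participant ranges — the dispersion statistic is declared explicitly
because a bare "median ± x" is ambiguous.

## Daily-rhythm detection

1. **Percent-of-maximum normalization.** Each within-day slice with ≥6
   samples of the analyte is divided by its own daily maximum (×100).
   Days with fewer samples cannot support a sine fit and are excluded
   (logged, not an error). The normalization makes profiles scale-free:
   multiplying a person's raw values by any positive constant changes
   nothing downstream (property-tested). The ratio is computed as
   `(v / max) * 100` so the maximum maps to exactly 100.0.
2. **Minute grid and interpolation.** Observed points are linearly
   interpolated onto a 1-minute grid between the first and last
   observation only — no extrapolation — and the observed minutes are
   retained in a mask.
3. **Aggregation.** The per-minute median (configurable to mean) across
   profiles, then a centered 2 h moving mean truncated at the profile's
   extent (no wraparound). Interpolation and smoothing serve the
   aggregate fit and visualization; inferential window tests never see
   interpolated values.
4. **Sum-of-sines fit.** `y(t) = d + Σₖ aₖ sin(bₖt + cₖ)` with each
   derived period `2π/bₖ` constrained to its configured bound — default
   10–12 h plus 23–25 h for the aggregate, 23–25 h only for individual
   profiles. The free offset `d` is essential: percent-of-max data live
   near 60–100, and without an offset no sum of sines can reach R² ≈ 0.9
   there; adjusted R² therefore uses p = 3K + 1 parameters. Optimization
   is scipy's trust-region reflective bounded least squares, restarted
   from a deterministic grid (phases {0, π/2, π, 3π/2} × periods
   {low, mid, high} per component, Cartesian across components, plus one
   near-flat start that guarantees the fit is never worse than a
   constant). Reported: SSE, RMSE = √(SSE/n), R², adjusted R², asymptotic
   95% parameter CIs from the Jacobian (the CI method is this package's
   choice), and the fitted curve's acrophase (argmax on a 1-minute
   grid). Constant input is flagged degenerate (R² undefined) rather
   than fitted. A deliberately mismatched signal (e.g. a 4 h sine under
   23–25 h bounds) pins the period to a bound and reports adjusted
   R² ≈ 0 — mismatch is surfaced, not hidden.
5. **Peak/trough window test.** Observed percent-of-max values pooled in
   a trough clock window (default 05:00–07:00 for TC, 09:00–11:00 for
   TG) are compared against a peak window (15:00–17:00 TC, 16:00–18:00
   TG) with a Kruskal-Wallis rank test; a Kolmogorov-Smirnov normality
   check on the pooled standardized values is recorded alongside, since
   its typical failure on these data is the reason a rank test is the
   primary comparison. Fully tied input returns H = 0, p = 1, flagged.
   α = 0.05 two-sided throughout.

## Synthetic cohort generator

The latent (noiseless) value for a participant with realized baseline
`B` is

```
L(t) = B · (1 + A_d cos(2π(t − φ_d)/P_d)) · (1 + A_u cos(2π(t − φ_u)/P_u))
       + M(day) + PP(t)
```

multiplicative daily (d) and ultradian (u) cosines (a disabled component
contributes factor 1), an additive menstrual envelope `M` (0 when
disabled) and additive postprandial TG bumps `PP`. Multiplicative
components are parameterized by *relative* amplitude because the
analysis is percent-of-max, which is scale-free; a relative amplitude
`A` yields a percent-of-max fluctuation of exactly `2A/(1+A)`
(identity-tested to 1e-9).

Defaults, which are the package's reference study conditions:

| parameter | default | rationale |
|---|---|---|
| cohort size | 13 | size of the within-day rhythm cohort emulated |
| baselines (mean ± SD, mg/dL) | TC 185 ± 25, HDL 55 ± 12, TG 150 ± 60 | typical adult lipid panels with wide between-person spread |
| TC daily component | 24 h, A = 0.25, acrophase 16:00 | ≈40% of-max fluctuation, late-afternoon peak, morning minima |
| TG daily component | 24 h, A ≈ 0.205, acrophase 16:00 | ≈34% of-max fluctuation |
| HDL daily component | none | arrhythmic negative-control channel |
| acrophase dispersion | 1 h SD between participants | individual phases differ; exact dispersion is unreported in humans free-living, 1 h is conservative and configurable |
| TG ultradian | 4 h period, A = 0.15, phase uniform per participant | ~4 h pulses; pulses are not clock-locked across people, so each participant draws an independent phase |
| hunger channel | cosine at the participant's ultradian phase + π, discretized at −0.5/0/0.5 into ordinals 0–3 | antiphase hunger–TG relationship; the four-point scale's exact mapping is this package's choice |
| menstrual envelope | off by default; 28-day cycle, peak day 14, 50 mg/dL span when enabled | follicular rise to a peak near likely ovulation, luteal fall |
| postprandial TG | off by default (gain 0, τ = 2 h) | minimal additive decay model; meal effects are not the target of the default conditions |
| measurement noise | multiplicative Normal, CV 4.15%, redrawn until positive | device imprecision is reported as %CV |
| sampling | hourly 06:00–22:00, one day | serial within-day self-testing |

Between-participant baselines are Normal draws redrawn while ≤10 mg/dL.
Everything is deterministic for a fixed seed (byte-identical CSV after
serialization, tested).

**What the generator does and does not emulate.** It reproduces the
multi-timescale *structure* the analysis assumes — daily and ultradian
multiplicative rhythms, a menstrual envelope, sparse clock-locked
sampling schemes, multiplicative device noise. It has no day-to-day
baseline drift, no meal-timing irregularity by default, no activity,
sleep or seasonal effects, and no device bias relative to a clinical
reference (self-vs-clinical pairs differ only by measurement noise, so
simulated total error is ≈ CV·√(2/π) ≈ 3.3%, smaller than real-device
disagreement). Consequently, passing tests demonstrate that the
*pipeline* recovers known structure and obeys its contracts — not that
free-living data of any particular cohort look like the simulation.
In particular, simulated across-morning variability is narrower than
real self-tracked data (noise plus morning-window phase only), and
simulated within-day ranges in mg/dL scale directly with the configured
relative amplitude times the baseline, which is larger than some printed
cohort medians elsewhere imply.

## Device quality statistics

Imprecision of a time-paired duplicate self-test is
`%CV = 100·SD(a,b)/mean(a,b)` with the n−1 SD (equivalently
`|a−b|/√2` over the mean). The two-point CV estimator is biased low:
its expectation under CV `c` is `c·√(2/π)`; a Monte-Carlo test pins
this. Inaccuracy ("total error") of a self-test against a time-paired
clinical value is `100·|self − ref|/ref` — deliberately the simple
percent-disagreement definition, not the CLSI bias + 1.96·CV
formulation, and deliberately asymmetric (the clinical draw is the
denominator). Pairs are linked by an explicit `pair_id`, never inferred
from timestamp proximity. The QC report aggregates per-pair, per-person
and cohort statistics, computes risk-category agreement between
self-tests and references, flags (never drops) large errors, and
compares against configurable standards: 8.9% total-error validity
standard, 4.45% manufacturer CV, 13% manufacturer average TE, 84–86%
category-agreement band.

## Numerical choices and degenerate inputs

- Period bounds are enforced in angular-frequency space
  (`b ∈ [2π/high, 2π/low]`); start periods are nudged 1e-9 inside the
  bounds so the optimizer starts strictly feasible.
- Band classification uses `searchsorted(..., side="right")`, making the
  lower boundary inclusive; an exhaustive linear-scan oracle confirms
  agreement on a 1 mg/dL grid.
- All-equal within-day values produce a valid constant-100 profile;
  all-tied window tests return p = 1 flagged; constant fit input returns
  a degenerate result rather than NaN crashes.
- The moving average uses a `2·half + 1`-minute centered window
  (121 minutes for 2 h) with truncation at the edges via minimum-1
  periods; it commutes with adding a constant (tested).
- Rejected CSV rows are counted and logged individually with row number
  and reason; a missing required column is a configuration error.

## Problem sizes

Default test and acceptance runs use 13–24 simulated participants,
one day of hourly sampling (17 points/analyte) or 28–30 mornings,
20 seeds for recovery/negative-control rate checks, 25–50 QC pairs, and
961-point minute grids for aggregate fits — sizes chosen to match the
sparse self-tracking regime the package targets while keeping any
single check in seconds.

## Known limitations

- The rhythm fit assumes a stationary within-day shape; multi-day
  detrending, Lomb-Scargle/wavelet periodograms and acrophase bootstrap
  CIs are out of scope.
- LDL-cholesterol is never computed (it is not directly measured by the
  targeted devices), and no composite risk scores or treatment logic
  exist.
- The "+/–" dispersion printed by some sources for medians is
  ambiguous; this package always reports the SD of per-participant
  ranges and labels it as such.
- With several qualifying days per participant, the within-day crossing
  record keeps the largest-range day; other single-day summaries
  (first day, pooled days) are one code path away but not exposed.
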