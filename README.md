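# excessmort

Weekly excess and exiguous mortality estimation with a modified
Farrington quasi-Poisson baseline.

## What this package is for

During a health crisis, the deaths a surveillance system *observes* can
exceed (excess) or fall short of (exiguous) the deaths a counterfactual
"ordinary year" would have produced — for reasons that are invisible in
cause-specific counts alone, such as healthcare-system strain shifting
end-of-life care from hospitals to nursing facilities or the home.
`excessmort` implements the full estimation pipeline for weekly death
counts stratified by **cause-of-death group** (ICD-10 code ranges for
respiratory disease, circulatory disease, malignant neoplasms, senility,
plus all causes excluding COVID-19), **place of death**
(hospitals/clinics, nursing and elderly-care facilities, home, other)
and **region**.

The real inputs of this kind of analysis are restricted vital-statistics
microdata, so the package ships a first-class synthetic-data generator
with the statistical structure the model assumes (log-linear trend,
annual seasonality, overdispersion, injected excess episodes, reporting
delay), and every stage is tested against it.

## The model

For each target week *t* and each stratum the expected count is
estimated from the preceding *b* years of weekly counts via an
overdispersed Poisson regression

```
log E[Y_t] = α + β t + γ' f(t),        Var[Y_t] = φ · E[Y_t]
```

where `f(t)` is a 9+1-level seasonal factor: one *reference* level for
weeks within ±*w* weeks of the target's position in the year
(circularly, mod 52), and nine equal blocks for the rest of the year.
Defaults are `b = 5` years (`b = 3` for respiratory disease), `w = 3`.
Past aberrations are downweighted by inverse squared Anscombe residuals
above a 2.58 cutoff, and the fit is repeated once.  Unlike the original
Farrington algorithm, the linear trend term is always retained (the
original's conditional trend drop is available as an option).

Prediction bounds are computed on the 2/3-power scale:

```
U/L = μ̂₀ · (1 ± z₀.₉₇₅ · (2/3) · √(φ̂ μ̂₀ + Var[μ̂₀]) / μ̂₀)^(3/2)
```

A week is flagged **excess** when the observed count exceeds U,
**exiguous** when it falls below L.  Excess deaths are reported as a
range `[observed − U, observed − expected]` (clipped at 0), exiguous
deaths as the mirror image, and percentages divide by the expected
count.  Cumulative summaries sum the weekly range endpoints.

Trailing provisional weeks can be corrected for reporting delay by
multiplicative completeness inflation estimated from a reporting
triangle (a deliberately simple nowcast; see `docs/methods.md`).

## Worked example

Simulate two strata over 2014–2020 — a national non-COVID all-cause
series averaging ~1000 deaths/week with a 4-week 20% excess episode
injected from 2019-12-30, and a small prefecture-level senility series —
then run the analysis and summarise the episode window:

```bash
excessmort simulate --scenario scenario.yaml --out sim
excessmort run --config config.yaml --counts sim/counts.csv --out results
excessmort summarize --results results --from 2019-12-30 --to 2020-01-26
```

which prints

```
             stratum  observed  excess_low  excess_high  exiguous_low  exiguous_high
NON_COVID_ALL_all_JP      5689         229         1080             0              0
    SENILITY_home_13       161           0            1             0             31
```

The national series shows 229–1080 cumulative excess deaths over the
four episode weeks (the injected truth was 20% above a ~1150/week
baseline, i.e. ~900 excess deaths — inside the range), while the small
senility series, which received no episode, shows essentially none.
The per-week table (`results/weekly_NON_COVID_ALL_all_JP.csv`) carries
the observed count, expected count, both bounds, the flag and the
weekly ranges:

```
week_start,observed,expected,lower,upper,flag,excess_low,excess_high,...
2019-12-30,1441,1120.5,899.48,1357.15,EXCESS,83.85,320.5,...
2020-01-06,1275,1147.29,923.49,1386.71,NONE,0.0,127.71,...
2020-01-13,1431,1153.51,928.33,1394.43,EXCESS,36.57,277.49,...
```

and `results/runs_NON_COVID_ALL_all_JP.csv` lists the maximal runs of
consecutive excess weeks.  `results/manifest.json` records the resolved
configuration (including the respiratory `b = 3` override), input
digests and per-stratum status.

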