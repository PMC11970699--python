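# Methods

## Data model

A *camp record* holds a population, a death count, a calendar interval in
1971 (March 25 – December 16), and a cause class that routes the count to
the rate parameters: `general` → baseline rate $b$ only (even inside the
monsoon); `monsoon_excess` → excess rate $m$ only (even outside the
June–September window — the hazard label, not the calendar, governs: the
Jambu Island cyclone row in early November is a monsoon-class hazard);
`all` → $b$ for the whole interval plus $m$ for its monsoon-overlap
fraction. The bundled table has 17 records: 3 general, 9 monsoon-excess,
5 all-cause; five rows resting purely on official counts are flagged
`official_source` for the undercount scenario.

## Person-time and calendar conventions

Person-time is the reported (final) camp population times the interval
duration, in million person-days. Durations are inclusive day counts
(`end − start + 1`); this reproduces every printed duration in the
bundled table (153, 8, …, 21). Using the final population over the whole
interval overstates exposure for camps that filled gradually, biasing
rates — and hence the toll — downward; the estimate is conservative in
this respect.

The monsoon window is June 1 – September 30. For partial overlaps two
counting conventions are provided: `inclusive` (both endpoints counted,
consistent with the duration convention; the default) and `paper`
(difference-style overlap count, one day less), which reproduces the
121/199 = 0.608 overlap fraction historically quoted for the 199-day
Banjetia & Lalbagh record. An interval lying wholly inside the window has
fraction 1 under either convention. The choice moves every downstream
number by well under 1%.

Aggregate population person-times are constants in the configuration
(1853.65 M person-days overall, 884.06 M during the monsoon), as derived
from the official cumulative-influx records. When a dated influx series
is available instead, `person_time_from_influx` integrates the
piecewise-linear cumulative curve exactly (trapezoids); the integral is
additive over windows and matches a dense-grid Riemann oracle to well
under 0.1%.

## Estimation

The 17 equations $b\,x_{b,i} + m\,x_{m,i} = r_i$ are solved by Huber
M-estimation without intercept on the raw counts: IRLS starting from the
least-squares solution, tuning constant $c = 1.345$, residual scale
re-estimated each iteration as median$|r|$/0.6745, iterated to a relative
coefficient change below 1e-8 (max 200 iterations). A residual scale
below 1e-9 of the response magnitude is treated as an exact fit. The
response is the raw death count, not the rate, and no heteroscedasticity
weighting is applied; the implementation agrees with the canonical robust
regression in R (`MASS::rlm`) and Python (statsmodels `RLM`, used as the
cross-check oracle in the tests) to at least four significant figures on
the bundled data. No non-negativity constraint is imposed; a negative
fitted rate (impossible for a hazard) raises a warning.

On the bundled table the fit gives b = 110.81 and m = 510.44 deaths per
million person-days. These differ substantially from the previously
published point estimates for the same records (174.03 and 369.51), which
we were unable to reproduce under any standard robust-regression variant,
day-count convention or row weighting — the published baseline value lies
outside the attainable range of weighted least-squares solutions of this
design altogether. The discrepancy matters little for the headline toll:
the likelihood surface is a long ridge along directions that leave
$b\,N_{\text{total}} + m\,N_{\text{monsoon}}$ nearly constant, so the
total toll (656,654 vs the published 649,249, +1.1%) and the
adjusted-scenario total (736,390 vs 742,399, −0.8%) agree closely even
though the individual coefficients do not. Ridge-stable quantities should
be preferred when interpreting this analysis; the individual rates are
weakly identified by seventeen heterogeneous records.

## Uncertainty

Source-data variability is measured by refitting with each record left
out and recomputing the total toll; the variance of the 17 totals (sample
variance, denominator $n-1$ by default, $n$ available) is added to the
binomial variance of the total (≈ the total itself). The excess-toll
variance adds the natural toll's binomial variance on independence
grounds; the combined SE is multiplied once by the 1.545 age-stratification
inflation factor, and the interval is ±2 inflated SDs.

Two caveats, both verified by simulation. First, this is the *raw
variance of the leave-one-out totals*, not a jackknife variance estimate:
the proper jackknife would multiply by $(n-1)^2/n \approx 15$ at
$n = 17$. On real data the LOO variance is dominated by genuine
between-source disagreement and the interval is wide; but on clean data
generated from the binomial model itself, the raw-LOO interval undercovers
(≈71–72% instead of the nominal ~95% over 200 replicates; jackknife
scaling restores ≈96%). The procedure is kept in its literal form because
it is the reproduction target, and the recovery experiment reports
coverage so the effect is visible. Second, the 17-point jackknife SE of
the robust coefficients is right-skewed — conservative on average but
occasionally collapsing — so per-replicate 3-SE intervals for $b$ and $m$
hold in about 90%, not 99%, of replicates.

## Undercount adjustment

Official crisis-era death counts are often undercounts; paired
official/unofficial cholera counts give a multiplicative correction of
2.489. The scenario multiplies the five official-source rows' deaths by
this factor, rounds half-up (reproducing the published adjusted counts
3,111 / 1,245 / 2,489 / 2,489 / 1,245), and reruns the pipeline
unchanged. At factor 1 the scenario is exactly the identity.

## Synthetic data

`simulate_camps` draws each camp's deaths from a single
Binomial(population × days, rate per person-day) — exactly the model the
inference assumes, rather than a day-by-day survival process. Defaults
emulate the study conditions: 17 camps, true rates 174 and 370 per
million person-days, populations log-uniform over 3,000–250,000 (the
observed range), intervals of 5–230 days inside the study window, cause
mix 3:9:5. What the generator does *not* emulate: correlated reporting
errors, within-camp population growth, age structure, or overdispersion
beyond binomial — so passing recovery tests show the estimator is correct
under its own assumptions, not that the historical records satisfy them.
An `underreport_factor` divides drawn counts before output and flags rows
official-source, letting the adjustment scenario be tested against known
truth (with the factor at 2.489 the adjusted refit is measurably closer
to truth than the unadjusted one).

`simulate_influx` produces monotone cumulative curves: a linear ramp, a
seeded logistic S-curve, or a 4-knot piecewise-linear curve whose two
interior knot values are solved (a 2×2 linear system, third knot fixed at
0.95 of the final total) so that the full-window and monsoon-window
person-time integrals match the configured aggregates. A curve rising
from zero at the official record start cannot satisfy both aggregate
integrals simultaneously, so the solved curve carries a positive initial
stock — consistent with the influx having begun before official
record-keeping.

Replicate $k$ of `recovery_experiment` uses seed `spec.seed + k`, so
per-replicate results are independent of the replicate count and fully
reproducible. All randomness flows through explicitly seeded generators;
there is no global random state.

## Numerical and design choices

- All rate arithmetic is in deaths per million person-days at full
  precision; per-1000-per-year values (factor 365/1000) and printed
  roundings like 46.575 are display-only. The natural toll is
  1853.65 × 17000/365 = 86,334.4.
- Adjusted counts round half-up (not banker's rounding), matching the
  published adjusted counts.
- Degenerate designs (an empty covariate column, collinearity, fewer than
  2 rows) raise a dedicated error, as does a leave-one-out subset that
  loses identifiability, naming the omitted row.
- Validation errors from the record reader name the offending row and
  field.

## Problem sizes

The full pipeline (17-row fit, 17 leave-one-out refits, the adjustment
scenario with its own LOO) runs in well under a second. The recovery
experiment uses 200 replicates in the tests (~7 s); examples use 50 for
brevity.

## Known limitations

- Rates for camps are attached to the *reported* interval and final
  population; no within-camp dynamics.
- No modelling of refugees outside camps (about a third of the
  population), births, wayside deaths, or post-war repatriation — all
  omissions that bias the toll downward.
- The age-stratification inflation (1.545) and undercount factor (2.489)
  are consumed as constants, not derived.
- The individual rate coefficients are weakly identified (see
  Estimation); only ridge-stable projections are robust to fitting
  conventions.
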