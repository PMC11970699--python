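# campmort

Excess-mortality estimation from refugee-camp death records, built around
the 1971 Bangladesh liberation-war refugee crisis. During that year some
9.9 million refugees crossed into India; no systematic mortality records
were kept, but seventeen camp-level death counts survive in surveys,
official statements and newspaper reports. `campmort` turns those sparse,
heterogeneous records into an estimate of the total and excess death toll
with a defensible uncertainty interval.

The package is aimed at quantitative epidemiologists and historians of
humanitarian crises: anyone who needs to project a handful of
camp-level death counts onto a whole displaced population.

## The model

Deaths in a pool of $n$ person-days at a small per-person-day death
probability $p$ are modelled binomially, $r \sim \mathrm{Bin}(n, p)$, so
$E(r) = np$ and, because $p$ is tiny, $V(r) \approx np$. Two hazard
parameters are estimated, both in deaths per million person-days:

- $b$ — the baseline death rate from everyday causes, applicable
  year-round;
- $m$ — the additional rate during the June–September monsoon (cholera
  and other epidemics, floods); the total monsoon rate is $b + m$.

Each camp record contributes one equation
$b\,x_{b,i} + m\,x_{m,i} = r_i$, where the exposures $x_{b,i}, x_{m,i}$
(million person-days) follow from the record's *cause class*: counts of
general deaths load on $b$ only, counts of monsoon-hazard deaths (cholera,
cyclone) on $m$ only, and all-cause counts on $b$ plus the monsoon-overlap
fraction of $m$. The 17 equations are solved by Huber robust regression
without intercept (IRLS, tuning constant $c = 1.345$, MAD residual scale)
— single extreme camps should not dominate the fit.

Fitted rates are projected onto the whole population's person-time
($N_{\text{total}} = 1853.65$, $N_{\text{monsoon}} = 884.06$ million
person-days, from the official cumulative-influx records):

$$\text{total toll} = b\,N_{\text{total}} + m\,N_{\text{monsoon}},$$

and the excess toll subtracts the natural toll expected at the peacetime
crude death rate of 17 per 1000 per year. The variance composes three
independent pieces — the two binomial variances (each ≈ its toll) and the
variance of the 17 leave-one-out refitted totals — and the combined SD is
inflated by 1.545 for age-stratified mortality heterogeneity. A
sensitivity scenario multiplies the five purely-official death counts by
an undercount factor of 2.489 and reruns everything.

## Worked example

```python
import campmort as cm

result = cm.run_pipeline("bundled")   # the packaged 17-row camp table
print(result.rates.b, result.rates.m)
print(result.tolls.total_toll, result.tolls.excess_toll, result.tolls.excess_ci)
```

Running `python examples/01_reproduce_death_toll.py` prints:

```
Fitted death rates (deaths per million person-days):
  baseline b       =   110.81
  monsoon excess m =   510.44

Projected death tolls (deaths):
  baseline  =    205,394.9   (b x 1853.65 M person-days)
  monsoon   =    451,258.9   (m x  884.06 M person-days)
  total     =    656,653.8
  natural   =     86,334.4   (peacetime CDR 17/1000/yr)
  excess    =    570,319.4   (total - natural)

Excess-toll 95% CI: (277,028, 863,611)
```

So the camps' baseline mortality ran several times the peacetime rate,
the monsoon multiplied it again, and roughly 570,000 more refugees died
than peacetime mortality would explain — with a wide interval reflecting
how much the seventeen source records disagree. The other examples cover
the undercount adjustment, parameter recovery on synthetic data, and
person-time integration of influx curves.

A thin CLI wraps the same pipeline:

```sh
campmort run --camps bundled --adjusted --out report.json
campmort simulate --replicates 200 --seed 1 --out recovery
```

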