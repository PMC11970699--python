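"""Synthetic camp records and influx curves for end-to-end testing.

The generator draws data from exactly the probability model the inference
assumes: each camp's death count is a single Binomial draw with index
``population x days`` (person-day trials) and success probability equal to
the applicable per-person-day rate (baseline, monsoon-excess, or their
mixture through the monsoon-overlap fraction). Optional under-reporting
divides the drawn counts by a factor before output, mimicking official
undercounts, and flags those rows as official-source so the adjustment
scenario can be exercised against a known truth.

Defaults emulate the bundled 1971 study conditions: 17 camps, true rates
near the crisis-scale values (b = 174, m = 370 deaths per million
person-days), populations log-uniform over the observed 3,000-250,000
range, and intervals inside the March 25 - December 16 study window.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math

import numpy as np
import pandas as pd

from .adjustment import adjusted_scenario
from .estimator import fit_rates
from .exposure import (
    InfluxSeries,
    build_design,
    duration_days,
    monsoon_fraction,
    person_time_from_influx,
)
from .records import STUDY_END, STUDY_START, CampRecord, CauseClass, StudyConfig
from .uncertainty import excess_with_ci, loo_variance

__all__ = [
    "SimulationSpec",
    "simulate_camps",
    "simulate_influx",
    "recovery_experiment",
]


@dataclasses.dataclass(frozen=True)
class SimulationSpec:
    """Forward-model parameters for a synthetic camp table."""

    n_camps: int = 17
    true_b: float = 174.0  # deaths per million person-days
    true_m: float = 370.0
    population_range: tuple[int, int] = (3_000, 250_000)
    date_span: tuple[dt.date, dt.date] = (STUDY_START, STUDY_END)
    # proportions over (general, monsoon_excess, all); bundled table has 3/9/5
    cause_mix: tuple[float, float, float] = (3 / 17, 9 / 17, 5 / 17)
    underreport_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_camps < 2:
            raise ValueError("need at least 2 camps")
        if self.true_b < 0 or self.true_m < 0:
            raise ValueError("true rates must be non-negative")
        if not math.isclose(sum(self.cause_mix), 1.0, abs_tol=1e-9):
            raise ValueError("cause_mix proportions must sum to 1")
        if self.underreport_factor < 1.0:
            raise ValueError("underreport_factor must be >= 1")
        lo, hi = self.population_range
        if not (0 < lo <= hi):
            raise ValueError("invalid population_range")

    def true_excess(self, config: StudyConfig) -> float:
        """The estimand implied by the true rates and the config person-times."""
        from .mortality import cdr_to_per_million_day

        total = config.pt_total * self.true_b + config.pt_monsoon * self.true_m
        return total - config.pt_total * cdr_to_per_million_day(config.cdr_peacetime)


_CAUSES = (CauseClass.GENERAL, CauseClass.MONSOON_EXCESS, CauseClass.ALL)


def simulate_camps(
    spec: SimulationSpec, config: StudyConfig, seed: int | None = None
) -> list[CampRecord]:
    """Draw a synthetic camp table from the binomial person-time model.

    ``seed`` overrides ``spec.seed``; the same seed reproduces the same
    records exactly. Raises ``ValueError`` if a specified rate implies a
    per-person-day death probability of 1 or more.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    start0, end0 = spec.date_span
    span_days = (end0 - start0).days + 1
    lo, hi = spec.population_range
    records = []
    for i in range(spec.n_camps):
        cause = _CAUSES[rng.choice(3, p=spec.cause_mix)]
        population = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
        population = min(max(population, lo), hi)
        days = int(rng.integers(5, min(231, span_days) + 1))
        offset = int(rng.integers(0, span_days - days + 1))
        start = start0 + dt.timedelta(days=offset)
        end = start + dt.timedelta(days=days - 1)
        probe = CampRecord(
            camp_name=f"synthetic-camp-{i + 1:02d}",
            state="synthetic",
            population=population,
            deaths=0,
            start_date=start,
            end_date=end,
            cause_class=cause,
            official_source=spec.underreport_factor > 1.0,
            source_note="synthetic record",
        )
        frac = monsoon_fraction(probe, config)
        if cause is CauseClass.GENERAL:
            rate = spec.true_b
        elif cause is CauseClass.MONSOON_EXCESS:
            rate = spec.true_m
        else:
            rate = spec.true_b + frac * spec.true_m
        p_day = rate / 1e6
        if p_day >= 1.0:
            raise ValueError(
                f"rate {rate} per million person-days implies a per-person-day "
                "death probability >= 1"
            )
        trials = population * duration_days(start, end)
        deaths = int(rng.binomial(trials, p_day))
        deaths = int(round(deaths / spec.underreport_factor))
        deaths = min(deaths, population)  # record invariant: deaths <= population
        records.append(probe.replace(deaths=deaths))
    return records


def _logistic_cdf(t: np.ndarray, mid: float, s: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(t - mid) / s))


def simulate_influx(
    total_refugees: float,
    span: tuple[dt.date, dt.date],
    shape: str = "linear",
    seed: int = 0,
    *,
    config: StudyConfig | None = None,
    target_total_pt: float | None = None,
    target_monsoon_pt: float | None = None,
) -> InfluxSeries:
    """Generate a monotone cumulative-influx curve reaching ``total_refugees``.

    Shapes: ``linear`` (straight ramp from zero), ``logistic`` (smooth
    S-curve, midpoint jittered by ``seed``), and ``piecewise`` (a 4-knot
    piecewise-linear curve whose two interior knot values are solved so the
    full-window and monsoon-window person-time integrals match
    ``target_total_pt`` / ``target_monsoon_pt``, in million person-days;
    defaults come from ``config``). The piecewise curve may start above
    zero: an initial stock of refugees already present at the window start.
    """
    start, end = span
    if end <= start:
        raise ValueError("invalid span")
    if total_refugees <= 0:
        raise ValueError("total_refugees must be positive")
    T = (end - start).days

    if shape == "linear":
        dates = (start, end)
        counts = (0.0, float(total_refugees))
        return InfluxSeries(dates, counts)

    if shape == "logistic":
        rng = np.random.default_rng(seed)
        mid = T * rng.uniform(0.25, 0.45)
        s = T * rng.uniform(0.06, 0.12)
        t = np.arange(0, T + 1, dtype=float)
        raw = _logistic_cdf(t, mid, s)
        cum = total_refugees * (raw - raw[0]) / (raw[-1] - raw[0])
        cum = np.maximum.accumulate(cum)
        dates = tuple(start + dt.timedelta(days=int(d)) for d in t)
        return InfluxSeries(dates, tuple(float(c) for c in cum))

    if shape == "piecewise":
        cfg = config or StudyConfig()
        I_full = (target_total_pt if target_total_pt is not None else cfg.pt_total) * 1e6
        I_mon = (
            target_monsoon_pt if target_monsoon_pt is not None else cfg.pt_monsoon
        ) * 1e6
        k1, k2 = cfg.monsoon_start, cfg.monsoon_end + dt.timedelta(days=1)
        if not (start < k1 < k2 < end):
            raise ValueError("piecewise shape needs the monsoon window inside the span")
        d1 = (k1 - start).days
        d2 = (k2 - k1).days
        d3 = (end - k2).days
        # knots: (start, a0), (k1, c1), (k2, c2), (end, total); fix c2 and
        # solve the two trapezoid-integral constraints linearly for a0, c1
        c2 = 0.95 * total_refugees
        c1 = 2.0 * I_mon / d2 - c2
        a0 = 2.0 * (I_full - I_mon - (c2 + total_refugees) / 2.0 * d3) / d1 - c1
        vals = (a0, c1, c2, float(total_refugees))
        if any(v < 0 for v in vals) or any(
            b < a for a, b in zip(vals, vals[1:])
        ):
            raise ValueError(
                "target person-time integrals are infeasible for a monotone "
                f"curve reaching {total_refugees} (knots {vals})"
            )
        dates = (start, k1, k2, end)
        return InfluxSeries(dates, vals)

    raise ValueError(f"unknown influx shape {shape!r}")


def recovery_experiment(
    spec: SimulationSpec,
    replicates: int,
    config: StudyConfig,
    *,
    run_adjustment: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Repeatedly simulate, refit and summarise parameter recovery.

    Returns a per-replicate table (estimates of b, m, the excess toll, its
    CI and whether it covers the true excess; plus the adjusted-scenario
    total when ``run_adjustment``) and a summary dict with bias, RMSE and
    CI coverage against the spec's truth. Replicate ``k`` uses seed
    ``spec.seed + k``, so results are reproducible and independent of
    ``replicates``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    truth_excess = spec.true_excess(config)
    rows_out = []
    for k in range(replicates):
        recs = simulate_camps(spec, config, seed=spec.seed + k)
        design = build_design(recs, config)
        rates = fit_rates(design, config)
        loo = loo_variance(design, config)
        tolls = excess_with_ci(rates, loo, config)
        row = {
            "replicate": k,
            "seed": spec.seed + k,
            "b_hat": rates.b,
            "m_hat": rates.m,
            "excess_hat": tolls.excess_toll,
            "ci_low": tolls.excess_ci[0],
            "ci_high": tolls.excess_ci[1],
            "covered": tolls.excess_ci[0] <= truth_excess <= tolls.excess_ci[1],
        }
        if run_adjustment:
            scen = adjusted_scenario(recs, config)
            row["adjusted_total"] = scen.tolls.total_toll
            row["adjusted_excess"] = scen.tolls.excess_toll
        rows_out.append(row)
    df = pd.DataFrame(rows_out)
    summary = {
        "replicates": replicates,
        "true_b": spec.true_b,
        "true_m": spec.true_m,
        "true_excess": truth_excess,
        "bias_b": float(df["b_hat"].mean() - spec.true_b),
        "bias_m": float(df["m_hat"].mean() - spec.true_m),
        "bias_excess": float(df["excess_hat"].mean() - truth_excess),
        "rmse_b": float(np.sqrt(((df["b_hat"] - spec.true_b) ** 2).mean())),
        "rmse_m": float(np.sqrt(((df["m_hat"] - spec.true_m) ** 2).mean())),
        "rmse_excess": float(
            np.sqrt(((df["excess_hat"] - truth_excess) ** 2).mean())
        ),
        "ci_coverage": float(df["covered"].mean()),
    }
    return df, summary
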