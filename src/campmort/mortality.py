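"""Rate-unit conversion and death-toll computation under the binomial model.

Deaths in a pool of ``n`` person-days at per-person-day death probability
``p`` are modelled as Binomial(n, p); because ``p`` is tiny the variance
is approximately the mean, so the SD of any toll equals the square root of
the toll. All internal arithmetic uses deaths per **million person-days**
at full precision; the per-1000-per-year display unit differs by the
factor 365/1000 (per-million-day x 0.365 = per-1000-year).
"""

from __future__ import annotations

import dataclasses
import enum

import math

from .estimator import RateEstimates
from .records import StudyConfig

__all__ = [
    "RateUnit",
    "RateValue",
    "convert_rate",
    "cdr_to_per_million_day",
    "natural_toll",
    "NaturalToll",
    "toll_components",
    "rate_ratio",
    "TollResult",
]

#: per-million-person-day -> per-1000-person-year multiplier
_PMD_TO_PKY = 365.0 / 1000.0


class RateUnit(str, enum.Enum):
    PER_MILLION_PERSON_DAY = "per_million_person_day"
    PER_1000_PERSON_YEAR = "per_1000_person_year"


@dataclasses.dataclass(frozen=True)
class RateValue:
    value: float
    unit: RateUnit


def convert_rate(rate: RateValue, target: RateUnit) -> RateValue:
    """Convert a death rate between the two supported units (exact factor 365/1000)."""
    if not isinstance(target, RateUnit):
        raise ValueError(f"unknown rate unit {target!r}")
    if rate.unit is target:
        return rate
    if rate.unit is RateUnit.PER_MILLION_PERSON_DAY:
        return RateValue(rate.value * _PMD_TO_PKY, target)
    if rate.unit is RateUnit.PER_1000_PERSON_YEAR:
        return RateValue(rate.value / _PMD_TO_PKY, target)
    raise ValueError(f"unknown rate unit {rate.unit!r}")


def cdr_to_per_million_day(cdr_per_1000_year: float) -> float:
    """Crude death rate per 1000/year -> deaths per million person-days."""
    return cdr_per_1000_year / _PMD_TO_PKY


@dataclasses.dataclass(frozen=True)
class NaturalToll:
    toll: float
    sd_binomial: float
    sd_adjusted: float
    ci: tuple[float, float]


def natural_toll(config: StudyConfig) -> NaturalToll:
    """Expected peacetime death toll over the aggregate person-time.

    toll = pt_total x CDR (converted to per-million-person-day at full
    precision, not via the rounded printed intermediate). The binomial SD
    is sqrt(toll); the adjusted SD multiplies it by the age-stratification
    inflation factor, and the CI extends ci_halfwidth_sds adjusted SDs
    either side.
    """
    rate = cdr_to_per_million_day(config.cdr_peacetime)
    toll = config.pt_total * rate
    sd = math.sqrt(toll)
    sd_adj = sd * config.age_inflation
    half = config.ci_halfwidth_sds * sd_adj
    return NaturalToll(
        toll=toll,
        sd_binomial=sd,
        sd_adjusted=sd_adj,
        ci=(toll - half, toll + half),
    )


def toll_components(
    rates: RateEstimates, config: StudyConfig
) -> tuple[float, float, float]:
    """(baseline, monsoon, total) death tolls from fitted rates.

    baseline = pt_total x b; monsoon = pt_monsoon x m; total is their sum.
    """
    baseline = config.pt_total * rates.b
    monsoon = config.pt_monsoon * rates.m
    return baseline, monsoon, baseline + monsoon


def rate_ratio(crisis_rate: RateValue, peacetime_rate: RateValue) -> float:
    """Crisis-to-peacetime death-rate ratio, units harmonised internally."""
    peace = convert_rate(peacetime_rate, crisis_rate.unit)
    if peace.value == 0:
        raise ZeroDivisionError("peacetime rate is zero")
    return crisis_rate.value / peace.value


@dataclasses.dataclass(frozen=True)
class TollResult:
    """All toll estimates with their variance components and the final CI."""

    natural_toll: float
    natural_sd_binomial: float
    natural_sd_adjusted: float
    natural_ci: tuple[float, float]
    baseline_toll: float
    monsoon_toll: float
    total_toll: float
    total_variance_binomial: float
    loo_variance: float
    total_variance: float
    excess_toll: float
    excess_se_unadjusted: float
    excess_sd_adjusted: float
    excess_ci: tuple[float, float]

    def __post_init__(self) -> None:
        if self.loo_variance < 0:
            raise ValueError("leave-one-out variance cannot be negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["natural_ci"] = list(self.natural_ci)
        d["excess_ci"] = list(self.excess_ci)
        return d
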