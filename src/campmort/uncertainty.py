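"""Leave-one-out variance of the total toll and the excess-toll interval.

With only 17 heterogeneous records, parameter uncertainty is assessed by a
leave-one-out resampling of the fitted *total toll*: the regression is
refitted 17 times with one record omitted and the total toll recomputed
each time; the variance of the 17 totals measures source-data variability.
(This is a jackknife over totals taken literally -- no (n-1)/n rescaling.)
The excess-toll variance composes three independent pieces:

    V(excess) = natural_toll + total_toll + V_loo

(the two binomial variances, each approximately equal to its mean toll,
plus the leave-one-out variance). The SE is inflated once at the end by
the age-stratification factor, and the CI extends ``ci_halfwidth_sds``
inflated SDs either side of the excess toll.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .estimator import RateEstimates, fit_rates, DegenerateDesignError
from .exposure import DesignRow
from .mortality import TollResult, natural_toll, toll_components
from .records import StudyConfig

__all__ = ["LooResult", "loo_variance", "jackknife_se_rates", "excess_with_ci"]


@dataclasses.dataclass(frozen=True)
class LooResult:
    """Leave-one-out totals and their variance."""

    loo_totals: np.ndarray  # one refitted total toll per omitted row
    loo_variance: float
    denominator_convention: str  # "n_minus_1" or "n"

    def to_dict(self) -> dict:
        return {
            "loo_totals": [float(t) for t in self.loo_totals],
            "loo_variance": self.loo_variance,
            "denominator_convention": self.denominator_convention,
        }


def _loo_fits(
    rows: list[DesignRow], config: StudyConfig
) -> list[RateEstimates]:
    if len(rows) < 3:
        raise ValueError("leave-one-out needs at least 3 design rows")
    import warnings

    fits = []
    for i, omitted in enumerate(rows):
        subset = rows[:i] + rows[i + 1 :]
        try:
            with warnings.catch_warnings():
                # sign flips in internal perturbation refits are expected
                warnings.simplefilter("ignore", UserWarning)
                fits.append(fit_rates(subset, config))
        except DegenerateDesignError as exc:
            raise DegenerateDesignError(
                f"design degenerate when omitting row {i} "
                f"({omitted.camp_name}): {exc}"
            ) from exc
    return fits


def loo_variance(rows: list[DesignRow], config: StudyConfig) -> LooResult:
    """Variance of the leave-one-out total tolls.

    The denominator follows ``config.loo_ddof`` (default 1, the sample
    variance with n-1).
    """
    totals = np.array(
        [toll_components(f, config)[2] for f in _loo_fits(rows, config)]
    )
    var = float(totals.var(ddof=config.loo_ddof))
    return LooResult(
        loo_totals=totals,
        loo_variance=var,
        denominator_convention="n_minus_1" if config.loo_ddof == 1 else "n",
    )


def jackknife_se_rates(
    rows: list[DesignRow], config: StudyConfig
) -> tuple[float, float]:
    """Jackknife standard errors of (b, m) from the leave-one-out refits."""
    fits = _loo_fits(rows, config)
    n = len(fits)
    bs = np.array([f.b for f in fits])
    ms = np.array([f.m for f in fits])
    factor = (n - 1) / n
    se_b = math.sqrt(factor * np.sum((bs - bs.mean()) ** 2))
    se_m = math.sqrt(factor * np.sum((ms - ms.mean()) ** 2))
    return se_b, se_m


def excess_with_ci(
    rates: RateEstimates, loo: LooResult, config: StudyConfig
) -> TollResult:
    """Compose all variance pieces into the final excess toll and its CI.

    The natural-toll variance entering the composition is the *unadjusted*
    binomial one; the age-stratification inflation multiplies the combined
    SE exactly once, at the end.
    """
    nat = natural_toll(config)
    baseline, monsoon, total = toll_components(rates, config)
    total_variance = total + loo.loo_variance  # binomial variance = mean
    excess = total - nat.toll
    excess_variance = nat.toll + total_variance
    if excess_variance < 0:
        raise ValueError("negative composed variance")
    se = math.sqrt(excess_variance)
    sd_adj = se * config.age_inflation
    half = config.ci_halfwidth_sds * sd_adj
    return TollResult(
        natural_toll=nat.toll,
        natural_sd_binomial=nat.sd_binomial,
        natural_sd_adjusted=nat.sd_adjusted,
        natural_ci=nat.ci,
        baseline_toll=baseline,
        monsoon_toll=monsoon,
        total_toll=total,
        total_variance_binomial=total,
        loo_variance=loo.loo_variance,
        total_variance=total_variance,
        excess_toll=excess,
        excess_se_unadjusted=se,
        excess_sd_adjusted=sd_adj,
        excess_ci=(excess - half, excess + half),
    )
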