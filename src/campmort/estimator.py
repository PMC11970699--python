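"""Robust estimation of the two death-rate parameters.

The model: for camp *i* with exposures ``x_b[i]`` and ``x_m[i]`` (million
person-days), the expected death count is ``b * x_b[i] + m * x_m[i]`` where
``b`` is the baseline death rate and ``m`` the monsoon-excess rate, both in
deaths per million person-days. The parameters are fitted by Huber
M-estimation on the raw counts, without intercept:

    minimise  sum_i rho_c( (deaths_i - b x_b,i - m x_m,i) / s )

solved by iteratively reweighted least squares (IRLS). The residual scale
``s`` is re-estimated each iteration as the median absolute residual
divided by 0.6745 (the normal-consistency constant), i.e. the MAD about
zero. With the tuning constant ``c = inf`` every weight is 1 and the fit
reduces to ordinary least squares.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

from .exposure import DesignRow, person_time
from .records import CampRecord, StudyConfig

__all__ = ["RateEstimates", "fit_rates", "camp_rate", "DegenerateDesignError"]

MAD_CONSISTENCY = 0.6745
MAX_ITERATIONS = 200
REL_TOL = 1e-8


class DegenerateDesignError(ValueError):
    """The design matrix cannot identify both rate parameters."""


@dataclasses.dataclass(frozen=True)
class RateEstimates:
    """Fitted rates (deaths per million person-days) with fit diagnostics."""

    b: float
    m: float
    converged: bool
    iterations: int
    scale: float  # robust residual scale, deaths
    weights: np.ndarray  # final per-row Huber weights, in (0, 1]

    def to_dict(self) -> dict:
        return {
            "b_per_million_person_day": self.b,
            "m_per_million_person_day": self.m,
            "converged": self.converged,
            "iterations": self.iterations,
            "scale": self.scale,
            "weights": [float(w) for w in self.weights],
        }


def _design_arrays(rows: list[DesignRow]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([[r.x_b, r.x_m] for r in rows], dtype=float)
    y = np.array([r.deaths for r in rows], dtype=float)
    return X, y


def _check_identifiable(X: np.ndarray) -> None:
    if X.shape[0] < 2:
        raise DegenerateDesignError("need at least 2 design rows")
    if not np.any(X[:, 0]) or not np.any(X[:, 1]):
        raise DegenerateDesignError(
            "a covariate column is identically zero; both rates must be "
            "informed by at least one row"
        )
    if np.linalg.matrix_rank(X) < 2:
        raise DegenerateDesignError("covariate columns are collinear")


def _huber_weights(resid: np.ndarray, scale: float, c: float) -> np.ndarray:
    if math.isinf(c) or scale == 0.0:
        return np.ones_like(resid)
    w = np.ones_like(resid)
    big = np.abs(resid) > c * scale
    w[big] = c * scale / np.abs(resid[big])
    return w


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    Xw = X * w[:, None]
    return np.linalg.solve(Xw.T @ X, Xw.T @ y)


def fit_rates(rows: list[DesignRow], config: StudyConfig) -> RateEstimates:
    """Fit (b, m) by Huber IRLS on the design rows, without intercept.

    Iterates to a relative coefficient change below 1e-8 (at most 200
    iterations, ``converged`` reporting the outcome). If the design rows
    came from data with no residual error the OLS start is already exact
    and the fit returns immediately. A negative fitted rate triggers a
    ``UserWarning`` (the model intends both rates to be positive hazards).
    """
    X, y = _design_arrays(rows)
    _check_identifiable(X)

    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    converged = False
    iterations = 0
    scale = 0.0
    weights = np.ones(len(y))
    scale_floor = 1e-9 * max(1.0, float(np.max(np.abs(y))))
    for iterations in range(1, MAX_ITERATIONS + 1):
        resid = y - X @ beta
        scale = float(np.median(np.abs(resid)) / MAD_CONSISTENCY)
        if scale < scale_floor:  # exact fit: all weights 1, nothing to iterate
            weights = np.ones_like(resid)
            converged = True
            break
        weights = _huber_weights(resid, scale, config.huber_c)
        new_beta = _wls(X, y, weights)
        rel = np.max(
            np.abs(new_beta - beta) / np.maximum(np.abs(new_beta), 1e-300)
        )
        beta = new_beta
        if rel < REL_TOL:
            converged = True
            break

    b, m = float(beta[0]), float(beta[1])
    if b < 0 or m < 0:
        warnings.warn(
            f"negative fitted rate (b={b:.4g}, m={m:.4g}); the person-time "
            "mortality model expects non-negative hazards",
            UserWarning,
            stacklevel=2,
        )
    return RateEstimates(
        b=b,
        m=m,
        converged=converged,
        iterations=iterations,
        scale=scale,
        weights=weights,
    )


def camp_rate(record: CampRecord) -> float:
    """Single-camp death rate: deaths per million person-days of exposure."""
    pt = person_time(record)
    if pt <= 0:
        raise ValueError(f"zero person-time for {record.camp_name}")
    return record.deaths / pt
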