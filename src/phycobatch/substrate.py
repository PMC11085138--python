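"""Biomass yield on carbon substrate (Y_X/S, g dry weight per g substrate).

Two estimators are provided for heterotrophic batch cultures:

* the endpoint method — divide the biomass gained over the batch by the
  initial substrate concentration, valid when the substrate is exhausted by
  the time growth stops;
* the consumption method — regress cumulative biomass increments on
  cumulative substrate consumed (through the origin, since the mass-balance
  line passes through (0, 0) by definition), using paired time series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    DomainError,
    InsufficientDataError,
    NegativeGrowthError,
    NoConsumptionError,
)

__all__ = ["SubstrateSeries", "YieldEstimate", "yield_endpoint", "yield_consumption"]


@dataclass(frozen=True)
class SubstrateSeries:
    """Substrate (glucose or acetate) concentration vs time, g L^-1."""

    times: np.ndarray
    concentration: np.ndarray
    substrate: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentration, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentration", c)
        if t.shape != c.shape or t.ndim != 1:
            raise DomainError("times and concentration must be 1-D arrays of equal length")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise DomainError("times must be strictly increasing")
        if np.any(~np.isfinite(c)) or np.any(c < 0):
            raise DomainError("concentrations must be finite and >= 0")


@dataclass(frozen=True)
class YieldEstimate:
    """Y_X/S with the method used and, for the regression, its R^2."""

    y: float
    method: str  # "endpoint" | "consumption"
    r_squared: float = float("nan")
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.y < 0:
            raise DomainError(f"yield must be >= 0, got {self.y}")


def yield_endpoint(
    x_final: float,
    x_initial: float,
    s_initial: float,
    s_final: float | None = None,
) -> YieldEstimate:
    """Endpoint yield (x_final - x_initial) / s_initial.

    Assumes the substrate was fully consumed when growth stopped.  If a
    measured final substrate concentration is supplied and exceeds 5% of the
    initial one, a warning is issued because that assumption fails (the
    estimate is then biased low).
    """
    if not np.isfinite(s_initial) or s_initial <= 0:
        raise DomainError(f"s_initial must be > 0, got {s_initial}")
    if x_final < x_initial:
        raise NegativeGrowthError(
            f"final biomass {x_final} below initial {x_initial}"
        )
    if s_final is not None and s_final > 0.05 * s_initial:
        warnings.warn(
            f"residual substrate {s_final:.3g} g/L exceeds 5% of initial "
            f"{s_initial:.3g} g/L; endpoint yield assumes full consumption",
            stacklevel=2,
        )
    return YieldEstimate(y=(x_final - x_initial) / s_initial, method="endpoint", n_points=2)


def yield_consumption(
    biomass_times,
    biomass,
    substrate: SubstrateSeries,
) -> YieldEstimate:
    """Yield from the regression of biomass formed on substrate consumed.

    The substrate series is linearly interpolated onto the biomass sampling
    times when the grids differ.  With increments dX_i = X_i - X_0 and
    dS_i = S_0 - S_i, the yield is the least-squares slope through the
    origin, sum(dX dS) / sum(dS^2); R^2 is reported against the through-
    origin line.
    """
    t = np.asarray(biomass_times, dtype=float)
    x = np.asarray(biomass, dtype=float)
    if t.shape != x.shape or t.ndim != 1:
        raise DomainError("biomass_times and biomass must be 1-D arrays of equal length")
    if t.size < 3:
        raise InsufficientDataError("need >= 3 paired time points")
    s = np.interp(t, substrate.times, substrate.concentration)
    dx = x - x[0]
    ds = s[0] - s
    if np.max(ds) <= 0:
        raise NoConsumptionError("substrate never decreases over the series")
    denom = float(np.sum(ds * ds))
    slope = float(np.sum(dx * ds)) / denom
    ss_res = float(np.sum((dx - slope * ds) ** 2))
    ss_tot = float(np.sum(dx * dx))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return YieldEstimate(y=max(slope, 0.0), method="consumption", r_squared=r2, n_points=int(t.size))
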