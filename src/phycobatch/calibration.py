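"""Turbidity-sensor calibration for multicultivator optical-density logs.

The in-situ turbidity sensors of tube multicultivators report an apparent
optical density (here ``od_sensor``) that falls progressively below the true
optical density measured in a bench spectrophotometer (``od_reference``) as
the culture gets dense.  Over the densities reached in batch culture the
ratio of the two signals is well described by an exponential in the sensor
reading,

    od_reference / od_sensor = a * exp(b * od_sensor),

with species- and condition-dependent constants ``a`` and ``b``.  This
module fits that relationship from dilution-series pairs, applies it to
correct sensor logs, and inverts it (used by the simulator to emit
sensor-space traces).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.special import lambertw
from scipy.stats import t as t_dist

from .errors import DomainError, InsufficientDataError

__all__ = [
    "CalibrationModel",
    "CalibrationPair",
    "IDENTITY",
    "correct_od",
    "invert_od",
    "fit_calibration",
    "generate_pairs",
    "compare_phase_fits",
    "PhaseFitContrast",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Constants of the exponential sensor-correction model.

    Attributes
    ----------
    a : float
        Dimensionless low-density correction factor (the ratio
        od_reference/od_sensor as od_sensor -> 0).  Must be positive.
    b : float
        Exponent per sensor-OD unit.  May be negative; zero gives a purely
        linear correction.
    label : str
        Species/condition tag the model was fitted for.
    n_pairs : int
        Number of dilution pairs used in the fit (0 for hand-set models).
    r_squared : float
        Coefficient of determination of the fit in the linearised space.
    """

    a: float
    b: float
    label: str = ""
    n_pairs: int = 0
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if not np.isfinite(self.a) or self.a <= 0:
            raise DomainError(f"calibration constant a must be positive, got {self.a}")
        if not np.isfinite(self.b):
            raise DomainError(f"calibration constant b must be finite, got {self.b}")


IDENTITY = CalibrationModel(a=1.0, b=0.0, label="identity")


class CalibrationPair(NamedTuple):
    """One dilution point: apparent sensor OD vs reference spectrophotometer OD."""

    od_sensor: float
    od_reference: float


def _as_nonnegative_array(od, name: str) -> np.ndarray:
    arr = np.asarray(od, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0):
        raise DomainError(f"{name} must be finite and >= 0")
    return arr


def correct_od(od_sensor, model: CalibrationModel):
    """Convert apparent sensor OD to corrected (reference-equivalent) OD.

    Applies ``od_sensor * a * exp(b * od_sensor)`` elementwise.  Accepts a
    scalar or array; returns the same shape.
    """
    arr = _as_nonnegative_array(od_sensor, "od_sensor")
    out = arr * model.a * np.exp(model.b * arr)
    return float(out) if np.isscalar(od_sensor) else out


def invert_od(od_corrected, model: CalibrationModel):
    """Recover the apparent sensor OD producing a given corrected OD.

    Solves x * a * exp(b x) = y.  For b != 0 the closed form is
    x = W0(b y / a) / b with W0 the principal Lambert-W branch (its argument
    is >= 0 for non-negative inputs whenever b >= 0, and stays above -1/e for
    the mildly negative b seen in practice); for b = 0 it is y / a.
    """
    arr = _as_nonnegative_array(od_corrected, "od_corrected")
    if model.b == 0.0:
        out = arr / model.a
    else:
        w = lambertw(model.b * arr / model.a, k=0)
        if np.any(np.abs(np.imag(w)) > 1e-12):
            raise DomainError("corrected OD outside the invertible range of the model")
        out = np.real(w) / model.b
    return float(out) if np.isscalar(od_corrected) else out


def _coerce_pairs(pairs: Iterable) -> tuple[np.ndarray, np.ndarray]:
    seq = [CalibrationPair(*p) for p in pairs]
    x = np.array([p.od_sensor for p in seq], dtype=float)
    y = np.array([p.od_reference for p in seq], dtype=float)
    return x, y


def fit_calibration(
    pairs: Iterable,
    label: str = "",
    min_od_sensor: float = 0.01,
) -> CalibrationModel:
    """Fit the correction constants from a dilution series.

    The model is exactly linear after taking logs of the signal ratio,

        ln(od_reference / od_sensor) = ln a + b * od_sensor,

    so the fit is ordinary least squares in that space: deterministic and
    free of starting-value sensitivity.  Pairs with ``od_sensor`` below
    ``min_od_sensor`` are excluded because the ratio amplifies noise near
    zero.

    Raises
    ------
    InsufficientDataError
        Fewer than two usable pairs after applying the floor.
    DomainError
        Non-positive sensor or reference values among the usable pairs.
    """
    x, y = _coerce_pairs(pairs)
    keep = x >= min_od_sensor
    x, y = x[keep], y[keep]
    if x.size < 2:
        raise InsufficientDataError(
            f"need >= 2 pairs with od_sensor >= {min_od_sensor}, got {x.size}"
        )
    if np.any(y <= 0):
        raise DomainError("od_reference must be positive for all fitted pairs")
    z = np.log(y / x)
    slope, intercept = np.polyfit(x, z, 1)
    fitted = intercept + slope * x
    ss_res = float(np.sum((z - fitted) ** 2))
    ss_tot = float(np.sum((z - z.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return CalibrationModel(
        a=float(np.exp(intercept)),
        b=float(slope),
        label=label,
        n_pairs=int(x.size),
        r_squared=float(r2),
    )


def generate_pairs(
    model: CalibrationModel,
    od_sensor_grid: Sequence[float],
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[CalibrationPair]:
    """Generate dilution-series pairs consistent with a model.

    With ``noise_sd`` > 0 the reference OD receives multiplicative Gaussian
    noise (relative sd), emulating spectrophotometer dilution scatter.
    """
    x = _as_nonnegative_array(od_sensor_grid, "od_sensor_grid")
    y = correct_od(x, model)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        y = y * (1.0 + noise_sd * rng.standard_normal(y.shape))
    return [CalibrationPair(float(xi), float(yi)) for xi, yi in zip(x, y)]


@dataclass(frozen=True)
class PhaseFitContrast:
    """Comparison of calibrations fitted separately on two growth phases.

    ``p_a`` / ``p_b`` are two-sided p-values for equality of the respective
    constants, from the OLS standard errors of the linearised fits.
    """

    model_first: CalibrationModel
    model_second: CalibrationModel
    delta_a: float
    delta_b: float
    p_a: float
    p_b: float


def _linearised_ses(pairs: Iterable, min_od_sensor: float) -> tuple[float, float, int]:
    # Standard errors of (ln a, b) from the linearised OLS fit.
    x, y = _coerce_pairs(pairs)
    keep = (x >= min_od_sensor) & (y > 0)
    x, y = x[keep], y[keep]
    z = np.log(y / x)
    n = x.size
    slope, intercept = np.polyfit(x, z, 1)
    resid = z - (intercept + slope * x)
    dof = n - 2
    s2 = float(np.sum(resid**2)) / max(dof, 1)
    sxx = float(np.sum((x - x.mean()) ** 2))
    se_b = np.sqrt(s2 / sxx)
    se_lna = np.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx))
    return se_lna, se_b, dof


def compare_phase_fits(
    pairs_first: Iterable,
    pairs_second: Iterable,
    labels: tuple[str, str] = ("exponential", "deceleration"),
    min_od_sensor: float = 0.01,
) -> PhaseFitContrast:
    """Fit each phase's dilution pairs separately and contrast the constants.

    Mirrors the practice of checking that a single calibration can serve a
    whole batch: if neither constant differs significantly between phases,
    one pooled model is adequate.
    """
    m1 = fit_calibration(pairs_first, label=labels[0], min_od_sensor=min_od_sensor)
    m2 = fit_calibration(pairs_second, label=labels[1], min_od_sensor=min_od_sensor)
    se1_lna, se1_b, dof1 = _linearised_ses(pairs_first, min_od_sensor)
    se2_lna, se2_b, dof2 = _linearised_ses(pairs_second, min_od_sensor)
    dof = max(dof1 + dof2, 1)

    def _p(diff: float, se: float) -> float:
        if se == 0:
            return 1.0 if diff == 0 else 0.0
        return float(2.0 * t_dist.sf(abs(diff) / se, dof))

    return PhaseFitContrast(
        model_first=m1,
        model_second=m2,
        delta_a=m2.a - m1.a,
        delta_b=m2.b - m1.b,
        p_a=_p(np.log(m2.a) - np.log(m1.a), float(np.hypot(se1_lna, se2_lna))),
        p_b=_p(m2.b - m1.b, float(np.hypot(se1_b, se2_b))),
    )
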