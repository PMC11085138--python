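"""Growth-phase segmentation and kinetic parameter estimation.

Light-limited photoautotrophic batch cultures show a short exponential phase
(constant specific growth rate mu, h^-1) followed by a long deceleration
("linear") phase in which self-shading makes biomass accumulation roughly
linear in time.  Two parameters summarise such a curve:

* mu — the slope of ln(OD) vs time over the exponential window
  (semi-logarithmic plot), with doubling time ln 2 / mu;
* V_max — the maximum volumetric biomass productivity (g L^-1 day^-1),
  taken from the steepest linear stretch of the deceleration phase after
  converting OD to biomass density.

Segmentation is deterministic: the exponential window is the longest window
whose log-OD linear fit reaches a configurable R^2 threshold, a reproducible
surrogate for picking the "linear part" of a semi-log plot by eye.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InsufficientDataError, NoExponentialPhaseError

__all__ = [
    "ODTimeSeries",
    "BiomassConversion",
    "PhaseSegmentation",
    "SegmentationConfig",
    "GrowthEstimate",
    "segment_phases",
    "estimate_mu",
    "doubling_time",
    "estimate_vmax",
    "od_to_biomass",
    "analyze_growth",
]


@dataclass(frozen=True)
class ODTimeSeries:
    """A sampled optical-density trace of one culture vessel.

    ``space`` records whether the values are raw sensor readings
    (``"sensor"``) or corrected, reference-equivalent OD (``"corrected"``).
    Times are hours since inoculation, strictly increasing, sampled on a
    uniform grid (within 1% jitter).
    """

    times: np.ndarray
    values: np.ndarray
    space: str = "corrected"
    channel: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or times.shape != values.shape:
            raise DomainError("times and values must be 1-D arrays of equal length")
        if times.size >= 2:
            dt = np.diff(times)
            if np.any(dt <= 0):
                raise DomainError("times must be strictly increasing")
            if dt.max() - dt.min() > 0.01 * dt.mean():
                raise DomainError("sampling interval must be constant within 1%")
        if np.any(~np.isfinite(values)) or np.any(values < 0):
            raise DomainError("OD values must be finite and >= 0")
        if self.space not in ("sensor", "corrected"):
            raise DomainError(f"space must be 'sensor' or 'corrected', got {self.space!r}")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class BiomassConversion:
    """Linear OD-to-biomass factor: grams dry weight per litre per corrected-OD unit."""

    k: float
    species: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.k) or self.k <= 0:
            raise DomainError(f"conversion factor k must be positive, got {self.k}")


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable thresholds of the phase-segmentation heuristic.

    lag_skip : hours ignored at the start of the trace (inoculation lag and
        sensor settling).
    min_exp_hours : minimum admissible exponential-window duration.
    r2_threshold : minimum R^2 of the log-OD linear fit for a window to
        qualify as exponential.
    vmax_window_hours : sliding-window length used to locate the steepest
        linear stretch of the deceleration phase.
    """

    lag_skip: float = 2.0
    min_exp_hours: float = 5.0
    r2_threshold: float = 0.9995
    vmax_window_hours: float = 12.0


@dataclass(frozen=True)
class PhaseSegmentation:
    exp_start: float
    exp_end: float
    dec_start: float
    dec_end: float
    exp_r_squared: float

    def __post_init__(self) -> None:
        if not (self.exp_start < self.exp_end <= self.dec_start < self.dec_end):
            raise DomainError("phase windows must satisfy exp_start < exp_end <= dec_start < dec_end")


@dataclass(frozen=True)
class GrowthEstimate:
    """Combined kinetic summary of one batch curve."""

    mu: float
    doubling_time: float
    vmax: float
    vmax_window: tuple[float, float]
    segmentation: PhaseSegmentation
    mu_r_squared: float
    vmax_r_squared: float
    diagnostics: dict = field(default_factory=dict)


def _ols_slope_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and R^2 of an OLS line fit; R^2 defined 0 for constant y."""
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    syy = float(np.sum((y - ym) ** 2))
    slope = sxy / sxx
    if syy == 0:
        return slope, 0.0
    r2 = (sxy * sxy) / (sxx * syy)
    return slope, r2


def segment_phases(
    series: ODTimeSeries,
    config: SegmentationConfig | None = None,
) -> PhaseSegmentation:
    """Locate the exponential and deceleration windows of a batch curve.

    The exponential window is the longest contiguous window that (i) starts
    no earlier than ``lag_skip`` hours, (ii) spans at least
    ``min_exp_hours``, and (iii) has a log-OD linear fit with
    R^2 >= ``r2_threshold``.  Ties on duration are broken by higher R^2,
    then earlier start.  The deceleration window runs from the exponential
    window's end to the end of the series.

    Raises :class:`NoExponentialPhaseError` (reporting the best R^2 found)
    when no window qualifies, e.g. for a non-growing culture.
    """
    if config is None:
        config = SegmentationConfig()
    t = series.times
    v = series.values
    if series.space != "corrected":
        raise DomainError("segment_phases expects a corrected-space series")
    if len(series) < 20:
        raise InsufficientDataError("need at least 20 points to segment phases")

    usable = (t >= config.lag_skip) & (v > 0)
    # candidate start indices must begin a contiguous positive run
    idx = np.flatnonzero(usable)
    if idx.size < 3:
        raise NoExponentialPhaseError("too few usable points after lag_skip")
    logv = np.full_like(v, np.nan)
    logv[v > 0] = np.log(v[v > 0])

    best = None  # (duration, r2, -start_time, i, j)
    best_r2_any = -np.inf
    # O(n^2) scan with per-start vectorised suffix statistics; n ~ 150.
    for i in idx:
        # window must be contiguous in the original grid and all-positive
        tail = np.flatnonzero(~usable[i:])
        j_max = (i + tail[0] - 1) if tail.size else (t.size - 1)
        if j_max <= i + 1:
            continue
        tt = t[i : j_max + 1]
        yy = logv[i : j_max + 1]
        n = np.arange(1, tt.size + 1, dtype=float)
        ct, cy = np.cumsum(tt), np.cumsum(yy)
        ct2, cy2 = np.cumsum(tt * tt), np.cumsum(yy * yy)
        cty = np.cumsum(tt * yy)
        sxx = ct2 - ct * ct / n
        syy = cy2 - cy * cy / n
        sxy = cty - ct * cy / n
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(syy > 0, (sxy * sxy) / (sxx * syy), 0.0)
        dur = tt - tt[0]
        ok = (dur >= config.min_exp_hours) & (n >= 3)
        if np.any(ok):
            best_r2_any = max(best_r2_any, float(np.max(r2[ok])))
        ok &= r2 >= config.r2_threshold
        if not np.any(ok):
            continue
        # longest qualifying end for this start
        k = np.flatnonzero(ok)[np.argmax(dur[ok])]
        cand = (float(dur[k]), float(r2[k]), -float(tt[0]), int(i), int(i + k))
        if best is None or cand > best:
            best = cand

    if best is None:
        msg = "no exponential window met the R^2 criterion"
        if np.isfinite(best_r2_any):
            msg += f" (best R^2 = {best_r2_any:.4f} < {config.r2_threshold})"
        raise NoExponentialPhaseError(msg, best_r2_any if np.isfinite(best_r2_any) else None)

    _, r2, _, i, j = best
    exp_start, exp_end = float(t[i]), float(t[j])
    dec_end = float(t[-1])
    dec_start = exp_end if exp_end < dec_end else float(t[-2])
    return PhaseSegmentation(
        exp_start=exp_start,
        exp_end=min(exp_end, dec_start),
        dec_start=dec_start,
        dec_end=dec_end,
        exp_r_squared=float(r2),
    )


def estimate_mu(series: ODTimeSeries, seg: PhaseSegmentation) -> tuple[float, float]:
    """Specific growth rate over the exponential window.

    Returns ``(mu, r_squared)`` where mu is the OLS slope of ln(OD) vs time
    (h^-1) on the semi-logarithmic plot, restricted to the window.
    """
    mask = (series.times >= seg.exp_start) & (series.times <= seg.exp_end)
    if int(mask.sum()) < 5:
        raise InsufficientDataError("exponential window must contain >= 5 points")
    v = series.values[mask]
    if np.any(v <= 0):
        raise DomainError("non-positive OD inside the exponential window")
    slope, r2 = _ols_slope_r2(series.times[mask], np.log(v))
    return float(slope), float(r2)


def doubling_time(mu: float) -> float:
    """Generation time ln 2 / mu, in hours."""
    if not np.isfinite(mu) or mu <= 0:
        raise DomainError(f"doubling time requires mu > 0, got {mu}")
    return math.log(2.0) / mu


def od_to_biomass(od, conv: BiomassConversion):
    """Biomass density (g L^-1) from corrected OD via the linear factor k."""
    arr = np.asarray(od, dtype=float)
    if np.any(arr < 0):
        raise DomainError("OD must be >= 0")
    out = conv.k * arr
    return float(out) if np.isscalar(od) else out


def estimate_vmax(
    series: ODTimeSeries,
    seg: PhaseSegmentation,
    conv: BiomassConversion,
    config: SegmentationConfig | None = None,
) -> tuple[float, tuple[float, float], float]:
    """Maximum volumetric biomass productivity over the deceleration phase.

    Slides a window of ``vmax_window_hours`` across the deceleration phase,
    fits OD vs time by OLS in each, and converts the steepest slope to
    g L^-1 day^-1 via ``24 * k * slope``.  Returns
    ``(vmax, (win_start, win_end), r_squared)`` for the winning window.
    """
    if config is None:
        config = SegmentationConfig()
    t, v = series.times, series.values
    mask = (t >= seg.dec_start) & (t <= seg.dec_end)
    ti, vi = t[mask], v[mask]
    if ti.size < 2 or ti[-1] - ti[0] < config.vmax_window_hours:
        raise InsufficientDataError(
            f"deceleration phase shorter than vmax window ({config.vmax_window_hours} h)"
        )
    dt = float(np.mean(np.diff(ti)))
    w = max(int(round(config.vmax_window_hours / dt)) + 1, 3)
    best_slope, best_win, best_r2 = -np.inf, (float(ti[0]), float(ti[0])), 0.0
    for s in range(0, ti.size - w + 1):
        slope, r2 = _ols_slope_r2(ti[s : s + w], vi[s : s + w])
        if slope > best_slope:
            best_slope, best_win, best_r2 = slope, (float(ti[s]), float(ti[s + w - 1])), r2
    vmax = 24.0 * conv.k * max(best_slope, 0.0)
    return float(vmax), best_win, float(best_r2)


def analyze_growth(
    series: ODTimeSeries,
    conv: BiomassConversion,
    config: SegmentationConfig | None = None,
) -> GrowthEstimate:
    """Segment a corrected batch curve and estimate mu, doubling time, V_max."""
    seg = segment_phases(series, config)
    mu, mu_r2 = estimate_mu(series, seg)
    vmax, win, vmax_r2 = estimate_vmax(series, seg, conv, config)
    return GrowthEstimate(
        mu=mu,
        doubling_time=doubling_time(mu) if mu > 0 else float("nan"),
        vmax=vmax,
        vmax_window=win,
        segmentation=seg,
        mu_r_squared=mu_r2,
        vmax_r_squared=vmax_r2,
        diagnostics={"channel": series.channel, "n_points": len(series)},
    )
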