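"""Mechanistic batch-culture simulator with sensor distortion and noise.

Two growth modes are generated, mirroring the experimental designs the
analysis stages are built for:

* **Light-limited photoautotrophy** — a flat-panel/tube culture of depth L
  illuminated from one side with incident intensity I0.  Light decays with
  depth by Beer-Lambert attenuation, I(z) = I0 exp(-sigma X z), and the
  local specific growth rate follows a saturating (Monod-form) response in
  irradiance.  The population grows at the depth-averaged rate

      mu_bar(X) = (1/L) int_0^L mu_max I(z) / (K_I + I(z)) dz
                = mu_max / (sigma X L) * ln[(K_I + I0) / (K_I + I0 e^{-sigma X L})],

  minus a maintenance rate.  Self-shading turns the early exponential phase
  into a long deceleration phase with nearly linear biomass accumulation,
  the phenomenology batch photobioreactor curves show.

* **Heterotrophy** — Monod growth on glucose or acetate in darkness, with
  yield-coupled substrate drawdown and an optional dark-decay factor that
  slows growth after a configurable onset unless weak light is supplied
  (emulating the empirical weak-light growth effect).

Simulated corrected OD is biomass / conversion_k; sensor-space traces are
produced by inverting the exponential sensor-correction model, and
replicate noise is multiplicative Gaussian with per-replicate seed
substreams.  All ground-truth quantities (initial specific rate, light-
limitation onset, yield) are exposed so the analysis stages can be tested
by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .calibration import CalibrationModel, IDENTITY, invert_od
from .errors import DomainError
from .growth import ODTimeSeries
from .substrate import SubstrateSeries

__all__ = [
    "CultureSpec",
    "SimulatedBatch",
    "depth_averaged_rate",
    "simulate_photoautotrophic",
    "simulate_heterotrophic",
    "apply_sensor_model",
    "simulate_batch",
    "PigmentEffects",
    "generate_pigment_tables",
    "generate_dilution_pairs",
]


@dataclass(frozen=True)
class CultureSpec:
    """Full parameterisation of one simulated batch culture.

    Irradiances are µmol photons m^-2 s^-1; concentrations g L^-1; rates
    h^-1.  ``sigma`` is the biomass light-attenuation coefficient expressed
    per unit biomass concentration (m^-1 per g L^-1), so the optical depth
    across the vessel is ``sigma * X * L``.
    """

    mode: str = "photoautotrophic"  # "photoautotrophic" | "heterotrophic"
    # photoautotrophic parameters
    I0: float = 300.0
    L: float = 0.03  # light path, m (small-diameter glass tube)
    sigma: float = 100.0  # m^-1 per (g L^-1); 0.1 m^2 g^-1
    K_I: float = 150.0  # half-saturation irradiance
    # shared kinetics
    mu_max: float = 0.20
    maintenance: float = 0.002
    X0: float = 0.02
    # heterotrophic parameters
    substrate: str = "glucose"
    S0: float = 15.0
    K_S: float = 0.1
    Y_true: float = 0.55
    dark_decay_rate: float = 0.0
    dark_decay_onset: float = 50.0
    weak_light: bool = False
    # observation model
    conversion_k: float = 0.40  # g L^-1 per corrected-OD unit
    calibration: CalibrationModel = IDENTITY
    noise_sd: float = 0.01
    n_replicates: int = 3
    sample_interval: float = 0.5
    duration: float = 72.0
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("photoautotrophic", "heterotrophic"):
            raise DomainError(f"unknown mode {self.mode!r}")
        positives = {"L": self.L, "sigma": self.sigma, "conversion_k": self.conversion_k,
                     "duration": self.duration, "sample_interval": self.sample_interval,
                     "X0": self.X0}
        for name, val in positives.items():
            if not np.isfinite(val) or val <= 0:
                raise DomainError(f"{name} must be positive and finite, got {val}")
        nonneg = {"I0": self.I0, "K_I": self.K_I, "mu_max": self.mu_max,
                  "maintenance": self.maintenance, "S0": self.S0, "K_S": self.K_S,
                  "Y_true": self.Y_true, "dark_decay_rate": self.dark_decay_rate,
                  "noise_sd": self.noise_sd}
        for name, val in nonneg.items():
            if not np.isfinite(val) or val < 0:
                raise DomainError(f"{name} must be >= 0 and finite, got {val}")
        if self.n_replicates < 1:
            raise DomainError("n_replicates must be >= 1")


@dataclass
class SimulatedBatch:
    """Generated batch data plus all ground truths needed for recovery tests."""

    spec: CultureSpec
    times: np.ndarray
    biomass: np.ndarray  # noiseless, g L^-1
    od_corrected: ODTimeSeries  # noiseless corrected-space trace
    od_sensor: list[ODTimeSeries] = field(default_factory=list)  # noisy, per replicate
    substrate: SubstrateSeries | None = None  # noiseless
    substrate_replicates: list[SubstrateSeries] = field(default_factory=list)
    pigments: pd.DataFrame | None = None
    truth: dict = field(default_factory=dict)


def depth_averaged_rate(X, spec: CultureSpec):
    """Depth-averaged specific growth rate mu_bar(X) (closed form), h^-1.

    Does not include maintenance.  Vectorised over X; the optically thin
    limit (sigma X L -> 0) reduces to the surface Monod factor
    mu_max I0 / (K_I + I0).
    """
    x = np.asarray(X, dtype=float)
    d = spec.sigma * x * spec.L  # optical depth
    surface = spec.mu_max * spec.I0 / (spec.K_I + spec.I0)
    with np.errstate(divide="ignore", invalid="ignore"):
        full = (spec.mu_max / np.where(d > 0, d, 1.0)) * np.log(
            (spec.K_I + spec.I0) / (spec.K_I + spec.I0 * np.exp(-d))
        )
    out = np.where(d > 1e-9, full, surface * (1.0 - d / 2.0 * spec.K_I / (spec.K_I + spec.I0)))
    return float(out) if np.isscalar(X) else out


def _sample_grid(spec: CultureSpec) -> np.ndarray:
    n = int(round(spec.duration / spec.sample_interval))
    return np.linspace(0.0, n * spec.sample_interval, n + 1)


def simulate_photoautotrophic(spec: CultureSpec) -> SimulatedBatch:
    """Integrate the light-limited batch and emit sampled noiseless series.

    The reported truth includes the initial specific growth rate
    (mu_bar(X0) - maintenance) and the light-limitation onset: the first
    time the depth-averaged rate falls below 95% of its inoculation value.
    """
    if spec.mode != "photoautotrophic":
        raise DomainError("spec.mode must be 'photoautotrophic'")
    t_eval = _sample_grid(spec)

    def rhs(t, y):
        return [(depth_averaged_rate(y[0], spec) - spec.maintenance) * y[0]]

    sol = solve_ivp(
        rhs, (0.0, t_eval[-1]), [spec.X0], t_eval=t_eval,
        method="RK45", rtol=1e-10, atol=1e-12, dense_output=True,
    )
    if not sol.success:  # pragma: no cover - defensive
        raise DomainError(f"integration failed: {sol.message}")
    X = sol.y[0]
    mu0 = depth_averaged_rate(spec.X0, spec) - spec.maintenance
    onset = _limitation_onset(sol, spec)
    batch = _package(spec, t_eval, X)
    batch.truth.update(
        initial_specific_rate=mu0,
        light_limitation_onset=onset,
        peak_productivity_per_day=float(np.max(24.0 * np.gradient(X, t_eval))),
    )
    return batch


def _limitation_onset(sol, spec: CultureSpec) -> float:
    """First time mu_bar(X(t)) < 0.95 * mu_bar(X0), inf if never reached."""
    mu_ref = depth_averaged_rate(spec.X0, spec)

    def f(t):
        return depth_averaged_rate(float(sol.sol(t)[0]), spec) - 0.95 * mu_ref

    t_end = float(sol.t[-1])
    if f(t_end) > 0:
        return float("inf")
    return float(brentq(f, 0.0, t_end, xtol=1e-6))


def simulate_heterotrophic(spec: CultureSpec) -> SimulatedBatch:
    """Integrate Monod growth with yield-coupled substrate drawdown.

    dX/dt = mu_eff X, dS/dt = -mu_eff X / Y_true, with
    mu_eff = mu_max S/(K_S + S) d(t) and d(t) an exponential dark-decay
    factor active after ``dark_decay_onset`` unless weak light is supplied.
    With dark_decay_rate = 0 the trajectory conserves the mass balance
    X - X0 = Y_true (S0 - S) exactly.
    """
    if spec.mode != "heterotrophic":
        raise DomainError("spec.mode must be 'heterotrophic'")
    if spec.S0 <= 0:
        raise DomainError("heterotrophic simulation requires S0 > 0")
    t_eval = _sample_grid(spec)

    def decay(t):
        if spec.weak_light or spec.dark_decay_rate == 0:
            return 1.0
        return float(np.exp(-spec.dark_decay_rate * max(0.0, t - spec.dark_decay_onset)))

    def rhs(t, y):
        X, S = y
        S = max(S, 0.0)
        mu_eff = spec.mu_max * S / (spec.K_S + S) * decay(t)
        return [mu_eff * X, -mu_eff * X / spec.Y_true]

    sol = solve_ivp(
        rhs, (0.0, t_eval[-1]), [spec.X0, spec.S0], t_eval=t_eval,
        method="RK45", rtol=1e-10, atol=1e-12,
    )
    if not sol.success:  # pragma: no cover - defensive
        raise DomainError(f"integration failed: {sol.message}")
    X = sol.y[0]
    S = np.clip(sol.y[1], 0.0, None)
    batch = _package(spec, t_eval, X)
    batch.substrate = SubstrateSeries(times=t_eval, concentration=S, substrate=spec.substrate)
    batch.truth.update(
        initial_specific_rate=spec.mu_max * spec.S0 / (spec.K_S + spec.S0),
        yield_true=spec.Y_true,
        final_biomass_limit=spec.X0 + spec.Y_true * spec.S0,
    )
    return batch


def _package(spec: CultureSpec, t_eval: np.ndarray, X: np.ndarray) -> SimulatedBatch:
    od_corr = ODTimeSeries(
        times=t_eval, values=X / spec.conversion_k, space="corrected", channel="truth"
    )
    return SimulatedBatch(spec=spec, times=t_eval, biomass=X, od_corrected=od_corr)


def apply_sensor_model(batch: SimulatedBatch) -> SimulatedBatch:
    """Attach sensor-space replicate traces (and noisy substrate replicates).

    The noiseless corrected OD is pushed through the inverse of the
    sensor-correction model, then each replicate receives multiplicative
    Gaussian noise (relative sd ``noise_sd``) from its own substream of the
    spec seed.  Substrate replicates, when present, use further substreams.
    """
    spec = batch.spec
    sensor_true = invert_od(batch.od_corrected.values, spec.calibration)
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(2 * spec.n_replicates)
    batch.od_sensor = []
    for r in range(spec.n_replicates):
        rng = np.random.default_rng(children[r])
        noisy = sensor_true * (1.0 + spec.noise_sd * rng.standard_normal(sensor_true.shape))
        batch.od_sensor.append(
            ODTimeSeries(times=batch.times, values=np.clip(noisy, 0.0, None),
                         space="sensor", channel=f"rep{r + 1}")
        )
    if batch.substrate is not None:
        batch.substrate_replicates = []
        for r in range(spec.n_replicates):
            rng = np.random.default_rng(children[spec.n_replicates + r])
            noisy = batch.substrate.concentration * (
                1.0 + spec.noise_sd * rng.standard_normal(batch.times.shape)
            )
            batch.substrate_replicates.append(
                SubstrateSeries(times=batch.times, concentration=np.clip(noisy, 0.0, None),
                                substrate=spec.substrate)
            )
    return batch


def simulate_batch(spec: CultureSpec) -> SimulatedBatch:
    """Simulate a batch in the requested mode and attach sensor replicates."""
    if spec.mode == "photoautotrophic":
        batch = simulate_photoautotrophic(spec)
    else:
        batch = simulate_heterotrophic(spec)
    return apply_sensor_model(batch)


def generate_dilution_pairs(spec: CultureSpec, n: int = 20, max_od_sensor: float = 2.0):
    """Dilution-series calibration pairs consistent with the spec's sensor model.

    Emulates measuring dilutions of a dense culture on both instruments;
    noise (relative sd ``noise_sd``) is applied to the reference OD using a
    dedicated substream of the spec seed.
    """
    from .calibration import generate_pairs

    grid = np.linspace(max_od_sensor / n, max_od_sensor, n)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2 * spec.n_replicates + 1)[-1])
    return generate_pairs(spec.calibration, grid, noise_sd=spec.noise_sd, rng=rng)


# ---------------------------------------------------------------------------
# pigment-table generation


@dataclass(frozen=True)
class PigmentEffects:
    """Effect structure of the pigment-table generator.

    Cell means are built multiplicatively from a per-pigment base content
    (%DW, the low-light exponential-phase level):

        mean = base * acclim(I) * phase_mult * substrate_mult
                    * weaklight_mult * suppression

    with the photoacclimation curve
    ``acclim(I) = c_min + (c_max - c_min) * K_A / (K_A + I)`` (strictly
    decreasing in irradiance when c_max > c_min).  Heterotrophic cells have
    no growth irradiance; their mean is anchored to the photoautotrophic
    deceleration-phase reference (the across-intensity average) scaled by
    ``suppression``, so a suppression of 0.23 makes the heterotrophic
    content 23% of that reference by construction.  Replicates receive
    relative Gaussian noise.
    """

    species: str = "synthetic"
    base: Mapping[str, float] = field(
        default_factory=lambda: {"chl_ab": 4.0, "lutein": 0.45, "carotene": 0.15}
    )
    c_min: float = 0.4
    c_max: float = 1.0
    K_A: float = 200.0
    phase_mult: float = 1.5
    substrate_mult: float = 1.0  # acetate relative to glucose
    weaklight_mult: float = 1.0  # weak light relative to darkness
    suppression: float = 0.25  # heterotrophic relative to photoautotrophic reference
    intensities: tuple[float, ...] = (100.0, 300.0, 500.0, 700.0)
    weak_light_level: float = 5.0
    noise_sd: float = 0.05
    n_replicates: int = 3
    seed: int = 0

    def acclim(self, I: float) -> float:
        return self.c_min + (self.c_max - self.c_min) * self.K_A / (self.K_A + I)


def generate_pigment_tables(
    effects: PigmentEffects,
    substrates: Sequence[str] = ("glucose", "acetate"),
) -> pd.DataFrame:
    """Long-format pigment table covering the full photo + hetero design.

    Photoautotrophic cells: every intensity x phase x pigment.
    Heterotrophic cells: every substrate x {dark, weak light} x pigment.
    Columns match :data:`phycobatch.pigments.TABLE_COLUMNS`.
    """
    rng = np.random.default_rng(np.random.SeedSequence(effects.seed))
    rows: list[dict] = []

    def _emit(mean: float, **meta):
        vals = mean * (1.0 + effects.noise_sd * rng.standard_normal(effects.n_replicates))
        for r, v in enumerate(vals, start=1):
            rows.append(dict(species=effects.species, replicate=r,
                             percent_dw=float(max(v, 0.0)), **meta))

    for pigment, base in effects.base.items():
        ref_cells = []
        for I in effects.intensities:
            for phase, mult in (("exponential", 1.0), ("deceleration", effects.phase_mult)):
                mean = base * effects.acclim(I) * mult
                _emit(mean, mode="photoautotrophic", light=float(I), substrate="",
                      phase=phase, pigment=pigment)
                if phase == "deceleration":
                    ref_cells.append(mean)
        reference = float(np.mean(ref_cells))
        for substrate in substrates:
            sub_mult = effects.substrate_mult if substrate == "acetate" else 1.0
            for light, wl_mult in ((0.0, 1.0), (effects.weak_light_level, effects.weaklight_mult)):
                mean = reference * effects.suppression * sub_mult * wl_mult
                _emit(mean, mode="heterotrophic", light=light, substrate=substrate,
                      phase="heterotrophic-sample", pigment=pigment)
    return pd.DataFrame(rows, columns=[
        "species", "mode", "light", "substrate", "phase", "pigment", "replicate", "percent_dw",
    ])
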