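"""End-to-end batch analysis: calibrate, correct, segment, estimate, report.

The pipeline mirrors the processing applied to multicultivator batch logs:
fit (or load) the sensor calibration, correct each channel, average
replicate channels, segment growth phases, estimate mu / doubling time /
V_max, then optionally add substrate-yield estimates and pigment contrasts.
Replicate channels are averaged after correction, matching the convention
of reporting means of three culture replicates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .calibration import CalibrationModel, correct_od, fit_calibration
from .errors import PhycobatchError, PipelineError
from .growth import (
    BiomassConversion,
    ODTimeSeries,
    SegmentationConfig,
    analyze_growth,
)
from .io import (
    read_calibration_json,
    read_calibration_pairs,
    read_od_log,
    read_pigment_table,
    read_substrate_table,
)
from .pigments import effect_table
from .substrate import yield_consumption, yield_endpoint

__all__ = ["RunConfig", "run_pipeline"]

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Inputs and thresholds of one pipeline run.

    Exactly one of ``calibration_file`` (a fitted model as JSON) or
    ``calibration_pairs_file`` (a dilution series to fit) must be given.
    ``substrate_file``/``pigment_file`` are optional stages.
    """

    od_log: str
    conversion_k: float
    calibration_file: str | None = None
    calibration_pairs_file: str | None = None
    substrate_file: str | None = None
    substrate_name: str = ""
    s_initial: float | None = None
    pigment_file: str | None = None
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    contrast_design: str = "all"
    alpha: float = 0.05
    out_dir: str | None = None
    seed: int = 0
    label: str = ""

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        seg = obj.pop("segmentation", None)
        cfg = cls(**obj)
        if seg:
            cfg.segmentation = SegmentationConfig(**seg)
        return cfg


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except (PhycobatchError, OSError, KeyError) as exc:
                raise PipelineError(name, exc) from exc
        return wrapper
    return deco


@_stage("sensor_calibration")
def _get_calibration(config: RunConfig) -> CalibrationModel:
    if (config.calibration_file is None) == (config.calibration_pairs_file is None):
        raise PhycobatchError(
            "exactly one of calibration_file or calibration_pairs_file is required"
        )
    if config.calibration_file:
        return read_calibration_json(config.calibration_file)
    pairs = read_calibration_pairs(config.calibration_pairs_file)
    return fit_calibration(pairs, label=config.label)


@_stage("sensor_calibration")
def _correct(series: list[ODTimeSeries], model: CalibrationModel) -> list[ODTimeSeries]:
    out = []
    for s in series:
        values = s.values if s.space == "corrected" else correct_od(s.values, model)
        out.append(ODTimeSeries(times=s.times, values=values,
                                space="corrected", channel=s.channel))
    return out


def _average(series: list[ODTimeSeries]) -> ODTimeSeries:
    base = series[0].times
    for s in series[1:]:
        if s.times.shape != base.shape or np.max(np.abs(s.times - base)) > 1e-9:
            raise PipelineError("growth_analysis",
                                PhycobatchError("replicate channels have differing time grids"))
    mean = np.mean([s.values for s in series], axis=0)
    return ODTimeSeries(times=base, values=mean, space="corrected", channel="mean")


@_stage("growth_analysis")
def _growth(series, conv, seg_config):
    mean_series = _average(series)
    return mean_series, analyze_growth(mean_series, conv, seg_config)


def run_pipeline(config: RunConfig) -> dict:
    """Run all applicable stages and return (and optionally write) the report.

    Stage failures raise :class:`PipelineError` naming the stage.  The
    report is a JSON-serialisable dict with a versioned schema; when
    ``config.out_dir`` is set it is also written to ``report.json`` there,
    along with a pigment contrast CSV when that stage ran.
    """
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "label": config.label,
        "thresholds": vars(config.segmentation).copy(),
    }
    model = _get_calibration(config)
    report["calibration"] = {
        "a": model.a, "b": model.b, "n_pairs": model.n_pairs, "r_squared": model.r_squared,
    }

    try:
        raw = read_od_log(config.od_log)
    except PhycobatchError as exc:
        raise PipelineError("io", exc) from exc
    corrected = _correct(raw, model)
    conv = BiomassConversion(k=config.conversion_k, species=config.label)
    mean_series, growth = _growth(corrected, conv, config.segmentation)
    report["growth"] = {
        "mu_per_h": growth.mu,
        "doubling_time_h": growth.doubling_time,
        "vmax_g_per_L_day": growth.vmax,
        "vmax_window_h": list(growth.vmax_window),
        "exponential_window_h": [growth.segmentation.exp_start, growth.segmentation.exp_end],
        "mu_r_squared": growth.mu_r_squared,
        "vmax_r_squared": growth.vmax_r_squared,
        "n_channels": len(corrected),
    }

    if config.substrate_file:
        try:
            sub = read_substrate_table(config.substrate_file, config.substrate_name)
            biomass = conv.k * mean_series.values
            cons = yield_consumption(mean_series.times, biomass, sub)
            s0 = config.s_initial if config.s_initial is not None else float(sub.concentration[0])
            endp = yield_endpoint(float(biomass[-1]), float(biomass[0]), s0,
                                  s_final=float(sub.concentration[-1]))
            report["yield"] = {
                "substrate": config.substrate_name or sub.substrate,
                "endpoint": endp.y,
                "consumption": cons.y,
                "consumption_r_squared": cons.r_squared,
            }
        except PhycobatchError as exc:
            raise PipelineError("substrate_yield", exc) from exc

    if config.pigment_file:
        try:
            table = read_pigment_table(config.pigment_file)
            contrasts = effect_table(table, design=config.contrast_design, alpha=config.alpha)
            report["pigments"] = {
                "n_records": int(len(table)),
                "n_contrasts": int(len(contrasts)),
                "n_significant": int(contrasts["significant"].sum()) if len(contrasts) else 0,
            }
        except PhycobatchError as exc:
            raise PipelineError("pigment_stats", exc) from exc
        if config.out_dir:
            Path(config.out_dir).mkdir(parents=True, exist_ok=True)
            contrasts.to_csv(Path(config.out_dir) / "pigment_contrasts.csv", index=False)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report
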