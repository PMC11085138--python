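"""Pigment-content normalisation and replicate-group statistics.

Pigment quantities (chlorophyll a+b, lutein, total carotene) are expressed
throughout as percent of biomass dry weight (%DW).  The module computes the
standard comparisons for a photoacclimation study:

* light-intensity contrasts against a reference intensity;
* growth-phase contrasts (deceleration vs exponential);
* carbon-source contrasts (acetate vs glucose) and weak-light vs darkness
  contrasts for heterotrophic cultures;
* heterotrophic content expressed as a percentage of the mean
  photoautotrophic deceleration-phase content averaged across incident
  light intensities.

Two-group comparisons use a two-sample t-test at a per-comparison alpha of
0.05 (pooled variance by default; Welch optional), with no multiple-testing
correction by default and a Benjamini-Hochberg option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError

__all__ = [
    "PigmentRecord",
    "ContrastResult",
    "percent_dw",
    "reference_percentage",
    "contrast",
    "effect_table",
    "PIGMENTS",
]

PIGMENTS = ("chl_ab", "lutein", "carotene")

#: Columns of a long-format pigment table.
TABLE_COLUMNS = [
    "species", "mode", "light", "substrate", "phase", "pigment", "replicate", "percent_dw",
]


@dataclass(frozen=True)
class PigmentRecord:
    """Replicate pigment contents for one experimental cell.

    ``condition`` carries either the incident light intensity
    (photoautotrophic, µmol m^-2 s^-1) or the substrate plus light flag
    (heterotrophic, e.g. ``"acetate+weak_light"``).
    """

    species: str
    condition: str
    phase: str  # "exponential" | "deceleration" | "heterotrophic-sample"
    pigment: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.pigment not in PIGMENTS:
            raise DomainError(f"unknown pigment {self.pigment!r}")
        if len(self.values) < 1:
            raise DomainError("at least one replicate value required")
        if any((not np.isfinite(v)) or v < 0 or v >= 100 for v in self.values):
            raise DomainError("%DW values must be finite, >= 0 and < 100")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass(frozen=True)
class ContrastResult:
    """One two-group comparison: difference of means, Welch p-value, flag."""

    estimate: float
    p_value: float
    significant: bool
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise DomainError(f"p-value out of [0, 1]: {self.p_value}")


def percent_dw(pigment_mass_ug: float, dry_weight_mg: float) -> float:
    """Pigment content as percent of dry weight from µg pigment per mg DW."""
    if not np.isfinite(dry_weight_mg) or dry_weight_mg <= 0:
        raise DomainError(f"dry weight must be > 0 mg, got {dry_weight_mg}")
    if pigment_mass_ug < 0:
        raise DomainError("pigment mass must be >= 0")
    return 100.0 * (pigment_mass_ug / 1000.0) / dry_weight_mg


def reference_percentage(
    het: PigmentRecord,
    photo_dec: Sequence[PigmentRecord],
) -> float:
    """Heterotrophic pigment content relative to the photoautotrophic reference.

    The reference is the mean deceleration-phase content averaged over the
    incident light intensities supplied (each intensity contributing the
    mean of its replicates).  Returns 100 * het mean / reference mean.
    """
    if len(photo_dec) < 2:
        raise DomainError("need photoautotrophic records for >= 2 intensities")
    for rec in photo_dec:
        if rec.species != het.species or rec.pigment != het.pigment:
            raise DomainError(
                "reference records must match the heterotrophic record's species and pigment"
            )
        if rec.phase != "deceleration":
            raise DomainError("reference records must be deceleration-phase")
    ref = float(np.mean([rec.mean for rec in photo_dec]))
    if ref <= 0:
        raise DomainError("reference mean content must be positive")
    return 100.0 * het.mean / ref


def contrast(group_a, group_b, alpha: float = 0.05, equal_var: bool = True) -> ContrastResult:
    """Two-sided two-sample t-test of group_b against group_a.

    The default is the pooled-variance (Student) test: with n = 3
    replicates per group it holds its nominal level exactly under
    normality, whereas the Welch approximation is measurably conservative
    at such tiny group sizes (true level ~0.035 at alpha = 0.05).  Pass
    ``equal_var=False`` for Welch when group variances genuinely differ.

    ``estimate`` is mean(group_b) - mean(group_a).  Two identical
    zero-variance groups are degenerate: p is set to 1 by convention and
    flagged.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("each group needs >= 2 replicate values")
    est = float(b.mean() - a.mean())
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if est == 0:
            return ContrastResult(estimate=0.0, p_value=1.0, significant=False, degenerate=True)
        return ContrastResult(estimate=est, p_value=0.0, significant=True, degenerate=True)
    p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
    return ContrastResult(estimate=est, p_value=p, significant=p < alpha)


def _cell(df: pd.DataFrame, **kv) -> np.ndarray:
    m = np.ones(len(df), dtype=bool)
    for col, val in kv.items():
        m &= df[col].to_numpy() == val
    return df.loc[m, "percent_dw"].to_numpy(dtype=float)


def effect_table(
    records: pd.DataFrame,
    design: str = "all",
    alpha: float = 0.05,
    reference_intensity: float = 300.0,
    fdr: bool = False,
) -> pd.DataFrame:
    """Run the study's contrast design over a long-format pigment table.

    ``records`` must carry the columns
    ``species, mode, light, substrate, phase, pigment, replicate, percent_dw``.
    Designs (``design="all"`` runs every applicable one):

    * ``light`` — photoautotrophic content at each intensity vs the
      reference intensity, per phase;
    * ``phase`` — deceleration vs exponential at each intensity;
    * ``substrate`` — heterotrophic acetate vs glucose (darkness);
    * ``weak_light`` — heterotrophic weak light vs darkness per substrate.

    Returns one row per contrast with the difference of means, Welch
    p-value and significance flag; design cells that are missing from the
    table are listed with ``status="missing"`` rather than raising.  With
    ``fdr=True`` a Benjamini-Hochberg adjustment replaces the per-comparison
    significance flags (off by default, matching per-comparison alpha).
    """
    if len(records) == 0:
        return pd.DataFrame(
            columns=["species", "pigment", "design", "cell", "estimate",
                     "p_value", "significant", "status"]
        )
    missing_cols = set(TABLE_COLUMNS) - set(records.columns)
    if missing_cols:
        raise DomainError(f"pigment table missing columns: {sorted(missing_cols)}")
    rows: list[dict] = []
    want = {"light", "phase", "substrate", "weak_light"} if design == "all" else {design}

    def _add(species, pigment, dsn, cell, ref_vals, vals):
        if ref_vals.size < 2 or vals.size < 2:
            rows.append(dict(species=species, pigment=pigment, design=dsn, cell=cell,
                             estimate=np.nan, p_value=np.nan, significant=False,
                             status="missing"))
            return
        res = contrast(ref_vals, vals, alpha=alpha)
        rows.append(dict(species=species, pigment=pigment, design=dsn, cell=cell,
                         estimate=res.estimate, p_value=res.p_value,
                         significant=res.significant, status="ok"))

    photo = records[records["mode"] == "photoautotrophic"]
    het = records[records["mode"] == "heterotrophic"]
    for species in sorted(records["species"].unique()):
        for pigment in sorted(records["pigment"].unique()):
            sp = photo[(photo["species"] == species) & (photo["pigment"] == pigment)]
            sh = het[(het["species"] == species) & (het["pigment"] == pigment)]
            intensities = sorted(sp["light"].unique())
            if "light" in want and len(sp):
                for phase in ("exponential", "deceleration"):
                    ref = _cell(sp, light=reference_intensity, phase=phase)
                    for inten in intensities:
                        if inten == reference_intensity:
                            continue
                        _add(species, pigment, "light", f"{phase}@{inten:g}v{reference_intensity:g}",
                             ref, _cell(sp, light=inten, phase=phase))
            if "phase" in want and len(sp):
                for inten in intensities:
                    _add(species, pigment, "phase", f"dec-v-exp@{inten:g}",
                         _cell(sp, light=inten, phase="exponential"),
                         _cell(sp, light=inten, phase="deceleration"))
            if "substrate" in want and len(sh):
                _add(species, pigment, "substrate", "acetate-v-glucose@dark",
                     _cell(sh, substrate="glucose", light=0.0),
                     _cell(sh, substrate="acetate", light=0.0))
            if "weak_light" in want and len(sh):
                for sub in sorted(sh["substrate"].unique()):
                    wl = sh[(sh["substrate"] == sub) & (sh["light"] > 0)]
                    wl_level = float(wl["light"].iloc[0]) if len(wl) else np.nan
                    _add(species, pigment, "weak_light", f"wl-v-dark@{sub}",
                         _cell(sh, substrate=sub, light=0.0),
                         _cell(sh, substrate=sub, light=wl_level) if len(wl) else np.array([]))
    out = pd.DataFrame(rows)
    if fdr and len(out):
        ok = out["status"] == "ok"
        p = out.loc[ok, "p_value"].to_numpy()
        if p.size:
            order = np.argsort(p)
            ranked = p[order] * p.size / (np.arange(p.size) + 1)
            adj = np.minimum.accumulate(ranked[::-1])[::-1]
            padj = np.empty_like(p)
            padj[order] = np.minimum(adj, 1.0)
            out.loc[ok, "p_adjusted"] = padj
            out.loc[ok, "significant"] = padj < alpha
    return out
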