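"""Bioanalytical method-validation statistics.

Implements the acceptance logic of a targeted LC-MS/MS validation:

* linearity — unweighted OLS of response vs nominal concentration over a
  ten-level two-fold dilution series; acceptable when r² > 0.99 on at
  least eight levels,
* sensitivity — LOD / LOQ as the lowest concentrations whose
  signal-to-noise exceeds 3 and 10 respectively (with all higher levels
  also passing),
* accuracy — measured/nominal within ±20% (single-point calibration),
* imprecision — CV (n−1 denominator) below 15%.

Semi-quantitative (a.u.) analytes carry no accuracy assessment; their
imprecision is computed on raw peak areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import AnalyteDef, panel_index

__all__ = [
    "R2_CRITERION",
    "MIN_LINEARITY_LEVELS",
    "LOD_SNR",
    "LOQ_SNR",
    "ACCURACY_BAND",
    "CV_CRITERION",
    "CalibrationLevel",
    "CalibrationSeries",
    "QCReplicateSet",
    "LinearityResult",
    "ValidationReport",
    "fit_linearity",
    "determine_lod_loq",
    "accuracy_percent",
    "cv_percent",
    "build_validation_report",
    "simulate_calibration_series",
    "simulate_qc_replicates",
]

R2_CRITERION = 0.99
MIN_LINEARITY_LEVELS = 8
LOD_SNR = 3.0
LOQ_SNR = 10.0
ACCURACY_BAND = (80.0, 120.0)
CV_CRITERION = 15.0


@dataclass(frozen=True)
class CalibrationLevel:
    nominal_conc: float
    response: float
    snr: float | None = None


@dataclass(frozen=True)
class CalibrationSeries:
    """Two-fold dilution calibration series, highest level first."""

    analyte: str
    levels: tuple[CalibrationLevel, ...]

    def __post_init__(self) -> None:
        concs = [lv.nominal_conc for lv in self.levels]
        for hi, lo in zip(concs, concs[1:]):
            if not np.isclose(hi / lo, 2.0, rtol=1e-6):
                raise ValueError(
                    f"{self.analyte}: levels not a strict two-fold series "
                    f"({hi} -> {lo})"
                )
        if any(lv.response < 0 for lv in self.levels):
            raise ValueError(f"{self.analyte}: negative response")


@dataclass(frozen=True)
class QCReplicateSet:
    """Replicates of one QC level (LQC/MQC/HQC) for one analyte."""

    analyte: str
    level: str
    nominal_conc: float
    within_run: tuple[float, ...]
    between_run: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.level not in ("LQC", "MQC", "HQC"):
            raise ValueError(f"unknown QC level {self.level!r}")
        for vals in (self.within_run, self.between_run):
            if len(vals) < 2:
                raise ValueError(f"{self.analyte}/{self.level}: need >= 2 replicates")
            if any(v <= 0 for v in vals):
                raise ValueError(f"{self.analyte}/{self.level}: non-positive value")


@dataclass(frozen=True)
class LinearityResult:
    slope: float
    intercept: float
    r2: float
    n_levels_used: int
    passed: bool


def fit_linearity(
    series: CalibrationSeries, level_mask: Sequence[bool] | None = None
) -> LinearityResult:
    """OLS line of response vs nominal concentration.

    ``level_mask`` selects the levels entering the fit (per-analyte
    dropping of top/bottom calibrators); r² is the squared Pearson
    correlation; pass requires r² > 0.99 on >= 8 levels.
    """
    levels = series.levels
    if level_mask is not None:
        if len(level_mask) != len(levels):
            raise ValueError("level mask length mismatch")
        levels = tuple(lv for lv, keep in zip(levels, level_mask) if keep)
    if len(levels) < 3:
        raise ValueError(f"{series.analyte}: need >= 3 levels, got {len(levels)}")
    x = np.array([lv.nominal_conc for lv in levels])
    y = np.array([lv.response for lv in levels])
    if np.ptp(y) == 0:
        raise ValueError(f"{series.analyte}: constant response, r2 undefined")
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    return LinearityResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=r2,
        n_levels_used=len(levels),
        passed=bool(r2 > R2_CRITERION and len(levels) >= MIN_LINEARITY_LEVELS),
    )


def determine_lod_loq(
    series: CalibrationSeries,
) -> tuple[float | None, float | None]:
    """LOD / LOQ from a signal-to-noise ladder.

    Each limit is the lowest concentration whose S/N exceeds the
    threshold with every higher concentration also exceeding it; None
    when no level qualifies.  LOQ >= LOD whenever both are determined.
    """
    levels = [lv for lv in series.levels if lv.snr is not None]
    if not levels:
        raise ValueError(f"{series.analyte}: no S/N data")
    # ascending concentration
    levels = sorted(levels, key=lambda lv: lv.nominal_conc)

    def lowest_sustained(threshold: float) -> float | None:
        best = None
        for lv in reversed(levels):  # from the top down while S/N holds
            if lv.snr > threshold:
                best = lv.nominal_conc
            else:
                break
        return best

    return lowest_sustained(LOD_SNR), lowest_sustained(LOQ_SNR)


def accuracy_percent(measured: float, nominal: float) -> tuple[float, bool]:
    """Recovery in percent with the ±20% acceptance flag."""
    if nominal <= 0:
        raise ValueError("nominal concentration must be positive")
    pct = 100.0 * measured / nominal
    return pct, ACCURACY_BAND[0] <= pct <= ACCURACY_BAND[1]


def cv_percent(values: Sequence[float]) -> tuple[float, bool]:
    """Coefficient of variation (%) with the <15% acceptance flag."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError("need >= 2 replicate values")
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("replicate mean must be positive")
    cv = 100.0 * vals.std(ddof=1) / mean
    return float(cv), bool(cv < CV_CRITERION)


@dataclass
class ValidationReport:
    """Per-analyte validation statistics and pass/fail flags."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def build_validation_report(
    series_list: Sequence[CalibrationSeries],
    qc_list: Sequence[QCReplicateSet],
    panel: Sequence[AnalyteDef],
) -> ValidationReport:
    """Assemble linearity, LOD/LOQ, accuracy and imprecision per analyte.

    Analytes without an internal standard get imprecision on raw areas
    and no accuracy figures.
    """
    idx = panel_index(panel)
    for qc in qc_list:
        if qc.analyte not in idx:
            raise ValueError(f"QC analyte {qc.analyte!r} not in panel")
    for s in series_list:
        if s.analyte not in idx:
            raise ValueError(f"calibration analyte {s.analyte!r} not in panel")

    rows: dict[str, dict] = {}

    def row(analyte: str) -> dict:
        return rows.setdefault(analyte, {"analyte": analyte})

    for s in series_list:
        r = row(s.analyte)
        lin = fit_linearity(s)
        r.update(
            slope=lin.slope,
            intercept=lin.intercept,
            r2=lin.r2,
            n_levels_used=lin.n_levels_used,
            linearity_pass=lin.passed,
        )
        if any(lv.snr is not None for lv in s.levels):
            lod, loq = determine_lod_loq(s)
            r.update(lod=lod, loq=loq)

    for qc in qc_list:
        r = row(qc.analyte)
        quantitative = idx[qc.analyte].has_internal_standard
        for tag, vals in (("within", qc.within_run), ("between", qc.between_run)):
            cv, cv_ok = cv_percent(vals)
            r[f"{qc.level}_{tag}_cv"] = cv
            r.setdefault("imprecision_pass", True)
            r["imprecision_pass"] = r["imprecision_pass"] and cv_ok
            if quantitative:
                acc, acc_ok = accuracy_percent(float(np.mean(vals)), qc.nominal_conc)
                r[f"{qc.level}_{tag}_accuracy"] = acc
                r.setdefault("accuracy_pass", True)
                r["accuracy_pass"] = r["accuracy_pass"] and acc_ok

    table = pd.DataFrame(list(rows.values()))
    return ValidationReport(table=table)


def simulate_calibration_series(
    analyte: str,
    top_conc: float,
    slope: float,
    n_levels: int = 10,
    noise_rel: float = 0.02,
    seed: int = 0,
    snr_top: float | None = None,
) -> CalibrationSeries:
    """Generate a two-fold dilution series with proportional response
    noise: response = slope * conc * (1 + eps), eps ~ N(0, noise_rel).

    When ``snr_top`` is given, S/N halves with each dilution, mirroring
    a signal-limited ladder.
    """
    rng = np.random.default_rng(seed)
    levels = []
    for i in range(n_levels):
        conc = top_conc / 2.0**i
        eps = noise_rel * rng.standard_normal()
        snr = None if snr_top is None else snr_top / 2.0**i
        levels.append(
            CalibrationLevel(
                nominal_conc=conc,
                response=max(slope * conc * (1.0 + eps), 0.0),
                snr=snr,
            )
        )
    return CalibrationSeries(analyte=analyte, levels=tuple(levels))


def simulate_qc_replicates(
    analyte: str,
    level: str,
    nominal_conc: float,
    n: int = 5,
    cv_true: float = 0.05,
    bias: float = 0.0,
    seed: int = 0,
) -> QCReplicateSet:
    """Generate within/between-run QC replicates with relative noise
    ``cv_true`` and a proportional bias."""
    rng = np.random.default_rng(seed)

    def draw() -> tuple[float, ...]:
        eps = cv_true * rng.standard_normal(n)
        return tuple(float(v) for v in nominal_conc * (1.0 + bias) * (1.0 + eps))

    return QCReplicateSet(
        analyte=analyte,
        level=level,
        nominal_conc=nominal_conc,
        within_run=draw(),
        between_run=draw(),
    )
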