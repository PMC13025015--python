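"""Synthetic reference and disease cohorts.

The reference population is modelled per analyte as an independent
log-normal: ``value = 10**(mu + sigma * N(0, 1))``.  For analytes with a
two-sided reference interval [L, U] the generating parameters are the
exact inversion of a parametric 95% interval on the log10 scale:

    mu    = (log10 L + log10 U) / 2
    sigma = (log10 U - log10 L) / (2 * 1.96)

Analytes reported upper-limit-only are, by construction, substantially
censored at the LOD in healthy children; their healthy parameters are
under-determined by the published limits, so they are anchored at the
LOD: with a default sigma of 0.25 log10 units, mu is chosen so that a
target fraction (default 20%, comfortably above the 2.5% upper-only
reporting threshold) of the population falls below LOD.

Disease cases shift each diagnostic marker by ``z_shift`` healthy-SD
units on the log10 scale, leaving residual spread and all non-marker
analytes at healthy levels.  Shipped default signatures give each of the
eleven studied disorders its textbook marker set (shift 6 for primary,
|4| for secondary markers; negative shifts model depletion, e.g. low
citrulline in OTC deficiency).
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import AnalyteDef, CohortTable, canonical_name

__all__ = [
    "AnalyteSimParams",
    "DiseaseSignature",
    "derive_sim_params_from_ri",
    "load_signatures",
    "simulate_reference_cohort",
    "simulate_disease_cases",
]

#: Central 95% z-multiplier used when inverting published limits.
Z_LIMIT = 1.96

DEFAULT_UPPER_ONLY_SIGMA = 0.25
DEFAULT_BELOW_LOD_TARGET = 0.20


@dataclass(frozen=True)
class AnalyteSimParams:
    """Log-normal generating parameters for one analyte."""

    name: str
    mu_log10: float
    sigma_log10: float
    lod: float
    below_lod_target: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_log10 < 0:
            raise ValueError(f"{self.name}: sigma_log10 must be >= 0")
        if not 0 <= self.below_lod_target < 1:
            raise ValueError(f"{self.name}: below_lod_target outside [0, 1)")


@dataclass(frozen=True)
class DiseaseSignature:
    """Marker shifts (in healthy-SD units, log10 scale) for one disease."""

    disease: str
    shifts: Mapping[str, float]


def derive_sim_params_from_ri(
    panel: Sequence[AnalyteDef],
    below_lod_target: float = DEFAULT_BELOW_LOD_TARGET,
    upper_only_sigma: float = DEFAULT_UPPER_ONLY_SIGMA,
) -> list[AnalyteSimParams]:
    """Invert panel reference intervals into log-normal parameters.

    Two-sided analytes invert [L, U] exactly; upper-only analytes are
    anchored so that ``below_lod_target`` of the healthy mass lies below
    the LOD with ``sigma_log10 = upper_only_sigma``.
    """
    params = []
    for a in panel:
        if a.ri_upper is None:
            raise ValueError(f"{a.name}: no reference interval to invert")
        lod = a.lod if a.lod is not None else 0.0
        if a.upper_only:
            # P(log10 X < log10 LOD) = target  =>  mu = log10 LOD - z_t * sigma
            if lod <= 0:
                raise ValueError(f"{a.name}: upper-only analyte needs LOD > 0")
            z_t = stats.norm.ppf(below_lod_target)
            mu = np.log10(lod) - z_t * upper_only_sigma
            params.append(
                AnalyteSimParams(a.name, float(mu), upper_only_sigma, lod,
                                 below_lod_target)
            )
        else:
            low, up = a.ri_lower, a.ri_upper
            if low is None or low <= 0 or up <= low:
                raise ValueError(f"{a.name}: invalid limits {low!r}, {up!r}")
            lo, hi = np.log10(low), np.log10(up)
            mu = (lo + hi) / 2.0
            sigma = (hi - lo) / (2.0 * Z_LIMIT)
            params.append(AnalyteSimParams(a.name, float(mu), float(sigma), lod))
    return params


def load_signatures(path: str | Path = "default") -> dict[str, DiseaseSignature]:
    """Load disease signatures from JSON, or the packaged defaults."""
    if path == "default":
        ref = importlib.resources.files("iemscreen.data") / "disease_signatures.json"
        raw = json.loads(ref.read_text())
    else:
        raw = json.loads(Path(path).read_text())
    return {
        disease: DiseaseSignature(
            disease,
            {canonical_name(m): float(s) for m, s in shifts.items()},
        )
        for disease, shifts in raw.items()
    }


def _draw(
    params: Sequence[AnalyteSimParams],
    n: int,
    rng: np.random.Generator,
    shifts: Mapping[str, float],
    label: str,
    id_prefix: str,
) -> CohortTable:
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    names = [p.name for p in params]
    unknown = set(shifts) - set(names)
    if unknown:
        raise ValueError(f"unknown marker analytes: {sorted(unknown)}")
    cols = {}
    flags = {}
    for p in params:
        mu = p.mu_log10 + shifts.get(p.name, 0.0) * p.sigma_log10
        log10_vals = mu + p.sigma_log10 * rng.standard_normal(n)
        vals = np.power(10.0, log10_vals)
        cols[p.name] = vals
        flags[p.name] = vals < p.lod
    index = pd.Index([f"{id_prefix}{i + 1}" for i in range(n)], name="sample_id")
    return CohortTable(
        values=pd.DataFrame(cols, index=index),
        below_lod=pd.DataFrame(flags, index=index),
        labels=pd.Series(label, index=index),
    )


def simulate_reference_cohort(
    params: Sequence[AnalyteSimParams], n: int, seed: int
) -> CohortTable:
    """Draw ``n`` healthy (control) profiles; deterministic given seed."""
    rng = np.random.default_rng(seed)
    return _draw(params, n, rng, {}, "control", "REF")


def simulate_disease_cases(
    params: Sequence[AnalyteSimParams],
    signature: DiseaseSignature,
    n: int,
    seed: int,
) -> CohortTable:
    """Draw ``n`` patient profiles for one disease signature."""
    rng = np.random.default_rng(seed)
    return _draw(
        params, n, rng, signature.shifts, signature.disease,
        f"{signature.disease}_",
    )
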