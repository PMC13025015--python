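"""Log10 z-score standardization against a reference cohort.

Each analyte's z-score is ``(log10 value - mean_log10) / sd_log10``
with moments taken over the full (imputed) reference cohort.  For
sparsely detected analytes — fewer than 100 reference observations
above the LOD — the empirical SD mostly reflects the imputation
constant, so it is replaced by a censoring-aware value calibrated so
that a measurement at five times the LOD scores z = 2.0:

    sd_log10 := (log10(5 * LOD) - mean_log10) / 2
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import AnalyteDef, CohortTable, panel_index

__all__ = ["N_VALID_THRESHOLD", "AnalyteZParams", "ZScoreModel",
           "fit_zscore_model", "compute_zscores"]

#: Minimum count of above-LOD reference observations for the empirical
#: SD to be trusted.
N_VALID_THRESHOLD = 100


@dataclass(frozen=True)
class AnalyteZParams:
    mean_log10: float
    sd_log10: float
    n_valid: int
    adjusted: bool
    lod: float

    def __post_init__(self) -> None:
        if self.sd_log10 <= 0:
            raise ValueError("sd_log10 must be positive")
        if self.adjusted and self.n_valid >= N_VALID_THRESHOLD:
            raise ValueError("adjusted model with enough valid data")


@dataclass
class ZScoreModel:
    """Per-analyte log10 mean/SD fitted on the reference cohort."""

    params: dict[str, AnalyteZParams]
    n_reference: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_reference": self.n_reference,
            "analytes": {
                name: {
                    "mean_log10": p.mean_log10,
                    "sd_log10": p.sd_log10,
                    "n_valid": p.n_valid,
                    "adjusted": p.adjusted,
                    "lod": p.lod,
                }
                for name, p in self.params.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ZScoreModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            params={
                name: AnalyteZParams(**entry)
                for name, entry in payload["analytes"].items()
            },
            n_reference=int(payload["n_reference"]),
        )


def fit_zscore_model(
    reference: CohortTable, panel: Sequence[AnalyteDef]
) -> ZScoreModel:
    """Fit per-analyte log10 moments on an imputed reference cohort.

    ``n_valid`` counts above-LOD reference observations (below-LOD cells
    carry no dispersion information once imputed to a constant); when
    it falls under 100, the 5xLOD rule replaces the SD.
    """
    idx = panel_index(panel)
    params: dict[str, AnalyteZParams] = {}
    for col in reference.analytes:
        a = idx.get(col)
        if a is None:
            raise ValueError(f"analyte {col!r} not in panel")
        vals = reference.values[col].to_numpy(dtype=float)
        if np.any(vals <= 0):
            raise ValueError(f"{col}: non-positive reference values (impute first)")
        log_vals = np.log10(vals)
        mean = float(np.mean(log_vals))
        n_valid = int((~reference.below_lod[col]).sum())
        lod = float(a.lod if a.lod is not None else 0.0)
        if n_valid < N_VALID_THRESHOLD:
            if lod <= 0:
                raise ValueError(f"{col}: 5xLOD adjustment needs a positive LOD")
            sd = (np.log10(5.0 * lod) - mean) / 2.0
            if sd <= 0:
                raise ValueError(
                    f"{col}: reference mean above log10(5*LOD); LOD and "
                    "reference data are inconsistent"
                )
            adjusted = True
        else:
            sd = float(np.std(log_vals, ddof=1))
            adjusted = False
        params[col] = AnalyteZParams(
            mean_log10=mean,
            sd_log10=float(sd),
            n_valid=n_valid,
            adjusted=adjusted,
            lod=lod,
        )
    return ZScoreModel(params=params, n_reference=reference.n_samples)


def compute_zscores(table: CohortTable, model: ZScoreModel) -> pd.DataFrame:
    """Z-score every cell of an imputed table against the model."""
    missing = [c for c in table.analytes if c not in model.params]
    if missing:
        raise ValueError(f"analytes missing from z-score model: {missing}")
    out = {}
    for col in table.analytes:
        p = model.params[col]
        vals = table.values[col].to_numpy(dtype=float)
        if np.any(vals <= 0):
            raise ValueError(f"{col}: non-positive values (impute first)")
        out[col] = (np.log10(vals) - p.mean_log10) / p.sd_log10
    return pd.DataFrame(out, index=table.values.index)
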