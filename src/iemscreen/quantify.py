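"""Value-level preprocessing: split-peak summation, single-point
calibration, and below-LOD imputation.

Two analytes (pyruvic acid and 3-methylglutaconic acid) chromatograph as
two peaks whose areas are summed before any downstream use.  Internal-
standardized analytes are quantified against a single calibrator via the
area-ratio rule.  Below-detection cells are imputed at the LOD for
quantitative analytes and at a fixed area of 2000 for area-reported
ones, so every value is strictly positive ahead of log10 / Box-Cox
transforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

from .panel import AnalyteDef, CohortTable, canonical_name, panel_index

__all__ = [
    "SPLIT_PEAK_ANALYTES",
    "AU_IMPUTE_AREA",
    "PeakRecord",
    "sum_split_peaks",
    "single_point_quantify",
    "impute_below_lod",
]

SPLIT_PEAK_ANALYTES = ("Pyruvic acid", "3-Methylglutaconic acid")

#: Fixed peak area assigned to below-LOD cells of a.u. analytes.
AU_IMPUTE_AREA = 2000.0


@dataclass(frozen=True)
class PeakRecord:
    """One integrated peak for one analyte in one sample."""

    sample_id: str
    analyte: str
    peak_label: str = ""
    area: float = 0.0
    is_area: float | None = None

    def __post_init__(self) -> None:
        if self.area < 0 or (self.is_area is not None and self.is_area < 0):
            raise ValueError(f"{self.sample_id}/{self.analyte}: negative peak area")


def sum_split_peaks(records: Sequence[PeakRecord]) -> list[PeakRecord]:
    """Collapse the two peaks of each split-peak analyte into their sum.

    Total area per sample per analyte is conserved; all other records
    pass through unchanged, in order.
    """
    out: list[PeakRecord] = []
    pending: dict[tuple[str, str], list[PeakRecord]] = {}
    order: list[tuple[str, str]] = []
    for rec in records:
        analyte = canonical_name(rec.analyte)
        if analyte in SPLIT_PEAK_ANALYTES:
            key = (rec.sample_id, analyte)
            if key not in pending:
                pending[key] = []
                order.append(key)
            pending[key].append(rec)
        else:
            out.append(rec)
    for key in order:
        group = pending[key]
        if len(group) > 2:
            raise ValueError(
                f"{key[0]}/{key[1]}: {len(group)} peaks for a split-peak analyte"
            )
        if len(group) == 1:
            warnings.warn(
                f"{key[0]}/{key[1]}: single peak for a split-peak analyte",
                stacklevel=2,
            )
            out.append(group[0])
        else:
            first = group[0]
            out.append(
                replace(
                    first,
                    peak_label="sum",
                    area=group[0].area + group[1].area,
                )
            )
    return out


def single_point_quantify(
    area: float,
    is_area: float,
    cal_area: float,
    cal_is_area: float,
    cal_conc: float,
) -> float:
    """Single-point calibration: concentration from IS-normalized ratios.

    conc = cal_conc * (area / is_area) / (cal_area / cal_is_area)
    """
    if is_area <= 0 or cal_is_area <= 0:
        raise ValueError("internal-standard area must be positive (IS failure)")
    if cal_area <= 0:
        raise ValueError("calibrator area must be positive")
    if area < 0:
        raise ValueError("analyte area must be non-negative")
    return cal_conc * (area / is_area) / (cal_area / cal_is_area)


def impute_below_lod(
    table: CohortTable, panel: Sequence[AnalyteDef]
) -> CohortTable:
    """Replace below-LOD cells: panel LOD for quantitative analytes, a
    fixed area of 2000 for a.u. analytes.  Flags are retained."""
    idx = panel_index(panel)
    out = table.copy()
    for col in out.analytes:
        a = idx.get(col)
        if a is None:
            raise ValueError(f"analyte {col!r} not in panel")
        fill = a.lod if a.quantitative else AU_IMPUTE_AREA
        mask = out.below_lod[col]
        out.values.loc[mask, col] = fill
    return out
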