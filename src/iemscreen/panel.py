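"""Analyte panel data model and measurement-table IO.

The panel describes a 54-analyte serum LC-MS/MS screen: 25 organic acids,
8 amino acids and 21 acylcarnitines.  34 analytes carry a stable-isotope
internal standard and are reported as concentrations (µmol/L); the rest
are reported semi-quantitatively as peak areas (a.u.).  Per-analyte
limits of detection/quantification, calibration ranges and the pediatric
(0-6 y) reference intervals ship with the package as the default panel.

Measurement tables are wide CSV/TSV (one sample per row, one column per
analyte); below-detection cells are represented as ``"<LOD"``.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ANALYTE_CLASSES",
    "DISEASE_LABELS",
    "AnalyteDef",
    "CohortTable",
    "MarkerPanelGroup",
    "canonical_name",
    "load_panel",
    "load_marker_groups",
    "read_measurements",
    "write_measurements",
]

ANALYTE_CLASSES = ("organic_acid", "amino_acid", "acylcarnitine")

#: Cohort labels: healthy controls plus the eleven studied inborn errors
#: of metabolism, with an escape hatch for anything else.
DISEASE_LABELS = (
    "control",
    "PA",
    "MMA",
    "IVA",
    "MCC",
    "GA2",
    "MCAD",
    "VLCAD",
    "CPT2",
    "TFP",
    "PKU",
    "OTC",
    "other",
)

BELOW_LOD_TOKEN = "<LOD"

# Source tables are inconsistent in punctuation (colon vs underscore in
# acylcarnitine names, stray dots, camel-case); map every observed spelling
# onto one canonical key.
_ALIASES = {
    "AC_C5_1": "AC_C5:1",
    "AC_C14_1": "AC_C14:1",
    "AC_C16_1": "AC_C16:1",
    "AC_C18_1": "AC_C18:1",
    "AC_C18_1OH": "AC_C18:1OH",
    "3-Methylglutaric.acid": "3-Methylglutaric acid",
    "3OH isovaleric acid": "3-Hydroxyisovaleric acid",
    "MethylsuccinicAcid": "Methylsuccinic acid",
    "EthylmalonicAcid": "Ethylmalonic acid",
}


def canonical_name(name: str) -> str:
    """Return the canonical panel spelling for an analyte name."""
    name = name.strip()
    return _ALIASES.get(name, name)


@dataclass(frozen=True)
class AnalyteDef:
    """Per-analyte panel metadata.

    ``lod``/``loq`` are expressed in the analyte's reporting units:
    µmol/L for quantitative (internal-standardized) analytes, peak area
    (a.u.) for semi-quantitative ones.  ``ri_lower`` is absent for
    analytes whose reference interval is reported upper-limit-only.
    """

    name: str
    analyte_class: str
    units: str  # "umol_per_L" | "au"
    internal_standard: str = ""
    lod: float | None = None
    loq: float | None = None
    cal_lower: float | None = None
    cal_upper: float | None = None
    ri_lower: float | None = None
    ri_upper: float | None = None

    def __post_init__(self) -> None:
        if self.analyte_class not in ANALYTE_CLASSES:
            raise ValueError(
                f"{self.name}: unknown analyte class {self.analyte_class!r}"
            )
        if self.units not in ("umol_per_L", "au"):
            raise ValueError(f"{self.name}: unknown units {self.units!r}")
        if self.units == "umol_per_L" and self.lod is None:
            raise ValueError(f"{self.name}: quantitative analyte without LOD")
        if self.lod is not None and self.loq is not None and self.lod > self.loq:
            raise ValueError(f"{self.name}: LOD {self.lod} exceeds LOQ {self.loq}")
        if (
            self.cal_lower is not None
            and self.cal_upper is not None
            and not self.cal_lower < self.cal_upper
        ):
            raise ValueError(f"{self.name}: empty calibration range")
        if (
            self.ri_lower is not None
            and self.ri_upper is not None
            and not self.ri_lower < self.ri_upper
        ):
            raise ValueError(f"{self.name}: empty reference interval")

    @property
    def quantitative(self) -> bool:
        """True when the analyte is concentration-reported (has an IS-backed
        calibration); a.u. analytes are semi-quantitative."""
        return self.units == "umol_per_L"

    @property
    def has_internal_standard(self) -> bool:
        return bool(self.internal_standard)

    @property
    def upper_only(self) -> bool:
        """Reference interval reported as an upper limit only."""
        return self.ri_upper is not None and self.ri_lower is None


@dataclass(frozen=True)
class MarkerPanelGroup:
    """A disease group sharing a metabolic pathway and its marker panel."""

    name: str
    diseases: tuple[str, ...]
    markers: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.diseases) < 2:
            raise ValueError(f"{self.name}: need at least two diseases per group")


@dataclass
class CohortTable:
    """Samples x analytes measurement table with below-LOD flags.

    ``values`` and ``below_lod`` are congruent DataFrames indexed by
    sample id; ``labels`` assigns each sample a cohort label (control or
    a disease).  Values are non-negative; after below-LOD imputation
    every value is strictly positive.
    """

    values: pd.DataFrame
    below_lod: pd.DataFrame
    labels: pd.Series
    age_months: pd.Series | None = None
    sex: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.below_lod.index) or not list(
            self.values.columns
        ) == list(self.below_lod.columns):
            raise ValueError("values and below_lod matrices are not congruent")
        if not self.values.index.equals(self.labels.index):
            raise ValueError("labels index does not match sample ids")
        bad = set(self.labels.unique()) - set(DISEASE_LABELS)
        if bad:
            raise ValueError(f"unknown cohort labels: {sorted(bad)}")
        finite = self.values.to_numpy(dtype=float)
        if np.nanmin(finite, initial=0.0) < 0:
            raise ValueError("negative measurement values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def analytes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def copy(self) -> "CohortTable":
        return CohortTable(
            values=self.values.copy(),
            below_lod=self.below_lod.copy(),
            labels=self.labels.copy(),
            age_months=None if self.age_months is None else self.age_months.copy(),
            sex=None if self.sex is None else self.sex.copy(),
        )

    def subset(self, labels: Sequence[str]) -> "CohortTable":
        mask = self.labels.isin(labels)
        return CohortTable(
            values=self.values.loc[mask],
            below_lod=self.below_lod.loc[mask],
            labels=self.labels.loc[mask],
        )

    def equals(self, other: "CohortTable", rtol: float = 0.0) -> bool:
        if self.sample_ids != other.sample_ids or self.analytes != other.analytes:
            return False
        if not self.labels.equals(other.labels):
            return False
        if not self.below_lod.equals(other.below_lod):
            return False
        a, b = self.values.to_numpy(float), other.values.to_numpy(float)
        return bool(np.allclose(a, b, rtol=rtol, atol=0.0))


def concat_cohorts(tables: Iterable[CohortTable]) -> CohortTable:
    """Stack cohorts sharing the same analyte columns."""
    tables = list(tables)
    cols = tables[0].analytes
    for t in tables[1:]:
        if t.analytes != cols:
            raise ValueError("cohorts have mismatched analyte columns")
    return CohortTable(
        values=pd.concat([t.values for t in tables]),
        below_lod=pd.concat([t.below_lod for t in tables]),
        labels=pd.concat([t.labels for t in tables]),
    )


def _parse_optional(x) -> float | None:
    if x is None or (isinstance(x, float) and np.isnan(x)) or x == "":
        return None
    return float(x)


def load_panel(path: str | Path = "default") -> list[AnalyteDef]:
    """Load an analyte panel from CSV/JSON, or the packaged default.

    The default panel has exactly 54 entries (25 organic acids, 8 amino
    acids, 21 acylcarnitines), 34 of them internal-standardized.
    """
    if path == "default":
        ref = importlib.resources.files("iemscreen.data") / "default_panel.csv"
        with importlib.resources.as_file(ref) as p:
            return load_panel(p)
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        rows = pd.read_csv(path, dtype=str).to_dict(orient="records")

    panel: list[AnalyteDef] = []
    seen: set[str] = set()
    for row in rows:
        name = canonical_name(str(row["name"]))
        if name in seen:
            raise ValueError(f"duplicate analyte name: {name}")
        seen.add(name)
        is_name = row.get("internal_standard") or ""
        if isinstance(is_name, float) and np.isnan(is_name):
            is_name = ""
        panel.append(
            AnalyteDef(
                name=name,
                analyte_class=str(row["analyte_class"]),
                units=str(row["units"]),
                internal_standard=str(is_name),
                lod=_parse_optional(row.get("lod")),
                loq=_parse_optional(row.get("loq")),
                cal_lower=_parse_optional(row.get("cal_lower")),
                cal_upper=_parse_optional(row.get("cal_upper")),
                ri_lower=_parse_optional(row.get("ri_lower")),
                ri_upper=_parse_optional(row.get("ri_upper")),
            )
        )
    return panel


def panel_index(panel: Sequence[AnalyteDef]) -> dict[str, AnalyteDef]:
    return {a.name: a for a in panel}


def load_marker_groups(path: str | Path = "default") -> dict[str, MarkerPanelGroup]:
    """Load disease-group marker panels (JSON), or the packaged defaults."""
    if path == "default":
        ref = importlib.resources.files("iemscreen.data") / "marker_groups.json"
        raw = json.loads(ref.read_text())
    else:
        raw = json.loads(Path(path).read_text())
    groups = {}
    for name, g in raw.items():
        groups[name] = MarkerPanelGroup(
            name=name,
            diseases=tuple(g["diseases"]),
            markers=tuple(canonical_name(m) for m in g["markers"]),
        )
    return groups


_META_COLUMNS = ("sample_id", "label", "age_months", "sex")


def read_measurements(
    path: str | Path, panel: Sequence[AnalyteDef]
) -> CohortTable:
    """Read a wide measurement CSV/TSV into a :class:`CohortTable`.

    Cells marked ``"<LOD"`` are flagged below-LOD and carry the standard
    imputed value (panel LOD for quantitative analytes, fixed area 2000
    for a.u. analytes).  Numeric cells falling below the panel LOD are
    flagged but keep their value.  Unknown analyte columns are rejected.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    raw = pd.read_csv(path, sep=sep, dtype=str)
    raw.columns = [
        c if c in _META_COLUMNS else canonical_name(c) for c in raw.columns
    ]
    idx = panel_index(panel)
    analyte_cols = [c for c in raw.columns if c not in _META_COLUMNS]
    unknown = [c for c in analyte_cols if c not in idx]
    if unknown:
        raise ValueError(f"unknown analyte columns: {unknown}")

    if "sample_id" in raw.columns:
        raw = raw.set_index("sample_id")
    else:
        raw.index = pd.Index([f"S{i + 1}" for i in range(len(raw))], name="sample_id")
    labels = (
        raw["label"].astype(str)
        if "label" in raw.columns
        else pd.Series("control", index=raw.index)
    )

    values = pd.DataFrame(index=raw.index, columns=analyte_cols, dtype=float)
    flags = pd.DataFrame(False, index=raw.index, columns=analyte_cols)
    for col in analyte_cols:
        a = idx[col]
        impute = a.lod if a.quantitative else 2000.0
        cells = raw[col].astype(str).str.strip()
        is_tok = cells == BELOW_LOD_TOKEN

        def _to_float(s: str) -> float:
            # Python's float() is correctly rounded; pandas' fast parser
            # can be off by one ulp, which would break round-tripping.
            try:
                return float(s)
            except ValueError:
                return float("nan")

        numeric = cells.where(~is_tok).map(_to_float, na_action="ignore")
        bad = numeric.isna() & ~is_tok
        if bad.any():
            sid = list(raw.index[bad])[0]
            raise ValueError(
                f"non-numeric cell in column {col!r}, sample {sid!r}: "
                f"{cells[bad].iloc[0]!r}"
            )
        if (numeric < 0).any():
            sid = list(raw.index[numeric < 0])[0]
            raise ValueError(f"negative value in column {col!r}, sample {sid!r}")
        values[col] = numeric.fillna(impute)
        flags[col] = is_tok | (
            numeric.notna() & (a.lod is not None) & (numeric < (a.lod or 0.0))
        )
    return CohortTable(values=values, below_lod=flags, labels=labels.str.strip())


def write_measurements(
    table: CohortTable, path: str | Path, panel: Sequence[AnalyteDef]
) -> None:
    """Write a :class:`CohortTable` to wide CSV.

    Flagged cells whose value equals the standard imputed constant are
    serialized as ``"<LOD"``; flagged cells still holding a raw
    (sub-LOD) numeric value are written numerically and will be
    re-flagged on read.  ``read_measurements`` round-trips the result.
    """
    idx = panel_index(panel)
    out = table.values.astype(object).copy()
    for col in table.analytes:
        a = idx.get(col)
        if a is None:
            raise ValueError(f"analyte {col!r} not in panel")
        impute = a.lod if a.quantitative else 2000.0
        flagged = table.below_lod[col]
        vals = table.values[col]
        censor = flagged & (vals.isna() | (vals == impute))
        out.loc[censor, col] = BELOW_LOD_TOKEN
        out.loc[~censor, col] = vals[~censor].map(lambda v: repr(float(v)))
    out.insert(0, "label", table.labels)
    out.index.name = "sample_id"
    out.to_csv(path)
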