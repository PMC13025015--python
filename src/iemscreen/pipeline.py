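"""End-to-end orchestration of the screening pipeline stages."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import classify, quantify, reference_intervals as ri, simulate, zscore
from .panel import AnalyteDef, CohortTable, MarkerPanelGroup, concat_cohorts

__all__ = [
    "derive_reference_intervals",
    "ri_table",
    "fit_group_model",
    "subseed",
]


def subseed(seed: int, stage: int) -> int:
    """Stable per-stage seed below 2**31 derived from one master seed."""
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


def derive_reference_intervals(
    reference: CohortTable,
    panel: Sequence[AnalyteDef],
    **ri_options,
) -> list[ri.ReferenceInterval]:
    """Impute a reference cohort and derive a reference interval per
    analyte; censoring fractions come from the pre-imputation flags."""
    imputed = quantify.impute_below_lod(reference, panel)
    out = []
    for a in panel:
        if a.name not in imputed.values.columns:
            continue
        frac = float(reference.below_lod[a.name].mean())
        out.append(
            ri.compute_ri(
                imputed.values[a.name].to_numpy(dtype=float), a, frac, **ri_options
            )
        )
    return out


def ri_table(intervals: Sequence[ri.ReferenceInterval]) -> pd.DataFrame:
    """Tabulate intervals the way a published RI table is laid out
    (upper-only rows render as '<= upper'), plus fit diagnostics."""
    rows = []
    for r in intervals:
        rows.append(
            {
                "analyte": r.analyte,
                "lower": None if r.upper_only else r.lower,
                "upper": r.upper,
                "interval": (
                    f"<={r.upper:.4g}"
                    if r.upper_only
                    else f"{r.lower:.4g}-{r.upper:.4g}"
                ),
                "upper_only": r.upper_only,
                "below_lod_fraction": r.below_lod_fraction,
                "lambda": None if r.fit is None else r.fit.lmbda,
                "n_retained": None if r.fit is None else r.fit.n_retained,
            }
        )
    return pd.DataFrame(rows)


def fit_group_model(
    group: MarkerPanelGroup,
    params: Sequence[simulate.AnalyteSimParams],
    signatures: dict[str, simulate.DiseaseSignature],
    model: zscore.ZScoreModel,
    panel: Sequence[AnalyteDef],
    n_controls: int,
    n_cases: dict[str, int],
    seed: int,
    l2_penalty: float = classify.DEFAULT_L2_PENALTY,
) -> tuple[classify.MLRModel, pd.DataFrame, pd.DataFrame, pd.Series]:
    """Simulate a screening cohort for one disease group, z-score it,
    and fit the group's multinomial model.

    Returns (model, confusion matrix, z matrix, labels).
    """
    cohorts = [
        simulate.simulate_reference_cohort(params, n_controls, subseed(seed, 100))
    ]
    for i, disease in enumerate(group.diseases):
        cohorts.append(
            simulate.simulate_disease_cases(
                params, signatures[disease], n_cases[disease],
                subseed(seed, 101 + i),
            )
        )
    cohort = concat_cohorts(cohorts)
    imputed = quantify.impute_below_lod(cohort, panel)
    z = zscore.compute_zscores(imputed, model)
    classes = ["control", *group.diseases]
    mlr = classify.fit_mlr(
        z, cohort.labels, group.markers, l2_penalty=l2_penalty, classes=classes
    )
    predicted = classify.predict_table(mlr, z)
    cm = classify.confusion_matrix(predicted, cohort.labels, classes)
    return mlr, cm, z, cohort.labels
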