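"""Clinical/qualitative predictor assembly, preprocessing and seizure-burden summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import SeizureAnnotation

__all__ = [
    "CLINICAL_MODEL_FIELDS",
    "QUALITATIVE_FIELDS",
    "SeizureMetrics",
    "preprocess_table",
    "seizure_metrics",
    "assemble_design",
    "DesignError",
]

#: Clinical predictors entering the clinical model, pre-encoding.
CLINICAL_MODEL_FIELDS = (
    "intrapartum_complications",
    "suspected_fetal_distress",
    "gestational_age",
    "delivery_mode",
    "male_gender",
    "birth_weight",
    "apgar_1",
    "apgar_5",
    "apgar_10",
    "assisted_ventilation_10min",
    "lowest_cord_ph",
    "first_base_excess",
    "first_lactate",
)

QUALITATIVE_FIELDS = (
    "discontinuity_abnormal",
    "discontinuity_gt10s",
    "low_voltage_or_isoelectric",
    "asymmetry_or_asynchrony",
    "swc_first_12h",
)

ADJUSTER_FIELDS = ("asm_before_epoch", "hypothermia")


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class SeizureMetrics:
    n_seizures: int
    total_burden_min: float
    max_hourly_burden_min: float
    status_epilepticus: bool
    seizure_period_h: float
    median_duration_s: float


def preprocess_table(
    table: pd.DataFrame, missing_threshold: float = 0.5
) -> tuple[pd.DataFrame, dict]:
    """One-hot encode, drop over-missing columns, mean-impute the rest.

    Columns whose missing fraction exceeds *missing_threshold* are dropped and
    listed in the report; remaining missing cells are replaced by the column
    mean over observed values, so observed-column means are preserved exactly.
    """
    if table.empty or table.isna().all().all():
        raise DesignError("table has no observed values to preprocess")
    encoded = pd.get_dummies(table, dtype=float)
    encoded = encoded.astype(float)

    frac = encoded.isna().mean()
    dropped = list(frac[frac > missing_threshold].index)
    kept = encoded.drop(columns=dropped)
    means = kept.mean()
    out = kept.fillna(means)
    report = {
        "dropped_columns": dropped,
        "imputed_cells": int(kept.isna().sum().sum()),
        "column_means": means.to_dict(),
    }
    return out, report


def _merge_events(events) -> list[tuple[float, float]]:
    merged: list[list[float]] = []
    for start, end in sorted(events):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def seizure_metrics(ann: SeizureAnnotation) -> SeizureMetrics:
    """Burden summaries; the hourly maximum uses a sliding 60-min window whose
    supremum is attained with a window boundary at an event boundary."""
    if not ann.events:
        return SeizureMetrics(0, 0.0, 0.0, False, 0.0, 0.0)
    events = _merge_events(ann.events)
    durations_s = [(e - s) * 3600.0 for s, e in ann.events]
    total_min = sum(e - s for s, e in events) * 60.0

    def burden_h(t0: float) -> float:
        t1 = t0 + 1.0
        return sum(max(0.0, min(e, t1) - max(s, t0)) for s, e in events)

    candidates = [s for s, _ in events] + [e - 1.0 for _, e in events]
    max_hourly_min = max(burden_h(t) for t in candidates) * 60.0
    return SeizureMetrics(
        n_seizures=len(ann.events),
        total_burden_min=total_min,
        max_hourly_burden_min=max_hourly_min,
        status_epilepticus=max_hourly_min > 30.0,
        seizure_period_h=events[-1][1] - events[0][0],
        median_duration_s=float(np.median(durations_s)),
    )


_MODES = {
    "clinical": ("clinical",),
    "qual": ("qualitative",),
    "quant": ("qeeg",),
    "clinical+qual": ("clinical", "qualitative"),
    "clinical+quant": ("clinical", "qeeg"),
}


def assemble_design(
    labels: pd.Series,
    mode: str,
    clinical: pd.DataFrame | None = None,
    qualitative: pd.DataFrame | None = None,
    qeeg: pd.DataFrame | None = None,
) -> tuple[list[pd.DataFrame], pd.Series]:
    """Per-mode feature matrices plus the label vector.

    Combination modes return the two single-mode matrices separately — model
    probabilities are fused downstream, features are never concatenated.
    Raw (unimputed) matrices are returned; imputation happens inside each
    training fold.
    """
    if mode not in _MODES:
        raise DesignError(f"unknown mode {mode!r}; expected one of {sorted(_MODES)}")
    sources = {"clinical": clinical, "qualitative": qualitative, "qeeg": qeeg}
    matrices: list[pd.DataFrame] = []
    for name in _MODES[mode]:
        table = sources[name]
        if table is None:
            raise DesignError(f"mode {mode!r} requires the {name} table")
        missing = labels.index.difference(table.index)
        extra = table.index.difference(labels.index)
        if len(missing) or len(extra):
            raise DesignError(
                f"{name} table does not align with labels; "
                f"missing subjects: {list(missing)}, unexpected subjects: {list(extra)}"
            )
        table = table.loc[labels.index]
        if name == "clinical":
            table = pd.get_dummies(table[list(CLINICAL_MODEL_FIELDS)], dtype=float)
            # unassisted vaginal delivery is the reference category
            table = table.drop(columns=["delivery_mode_unassisted_vaginal"], errors="ignore")
        elif name == "qualitative":
            table = table[list(QUALITATIVE_FIELDS)].astype(float)
        else:
            table = table.astype(float)
        matrices.append(table)
    return matrices, labels.astype(int)
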