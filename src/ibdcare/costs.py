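"""Per-patient resource-use and cost aggregation by care setting.

Encounters are first labelled with the disease-activity status of the
assessment period they fall in (half-open period rule; encounters outside the
period grid are dropped with a warning count). Aggregation is per-patient
first — each patient's visit count, inpatient length of stay, and GBP cost
total within a grouping cell, with zero-encounter patients contributing zeros
— and mean/SD are then taken across patients. Biologic drug costs are priced
per prescription from a tariff table (a configurable stand-in for
commissioner drug pricing).
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .activity import period_of
from .config import ActivityParams, CARE_TYPES

#: per-administration GBP tariffs for biologic products (stand-in values;
#: override via configuration for a real costing exercise)
DEFAULT_TARIFFS: Dict[str, float] = {
    "infliximab": 420.0,
    "infliximab-biosimilar": 300.0,
    "adalimumab": 350.0,
    "adalimumab-biosimilar": 250.0,
    "golimumab": 760.0,
    "vedolizumab": 2050.0,
    "ustekinumab": 2150.0,
}

GROUPING_KEYS = ("diagnosis_group", "status", "age_band", "care_type")


def attach_status(records: pd.DataFrame, observations: pd.DataFrame,
                  params: ActivityParams) -> Tuple[pd.DataFrame, int]:
    """Label dated per-patient rows with their assessment period and its
    status; returns (labelled rows, number dropped as outside all periods)."""
    out = records.copy()
    if len(out) == 0:
        out["period_index"] = pd.Series(dtype=int)
        out["status"] = pd.Series(dtype=object)
        return out, 0
    out["period_index"] = period_of(out["date"], params)
    n_outside = int(out["period_index"].isna().sum())
    out = out.dropna(subset=["period_index"]).copy()
    out["period_index"] = out["period_index"].astype(int)
    merged = out.merge(
        observations[["patient_id", "period_index", "status"]],
        on=["patient_id", "period_index"], how="left",
    )
    n_unmatched = int(merged["status"].isna().sum())
    merged = merged.dropna(subset=["status"])
    return merged.reset_index(drop=True), n_outside + n_unmatched


def price_biologic_prescriptions(prescriptions: pd.DataFrame,
                                 tariffs: Optional[Dict[str, float]] = None
                                 ) -> pd.DataFrame:
    """Biologic rows with a ``cost_gbp`` column from the tariff table
    (drug-name lookup, molecule fallback, otherwise 0)."""
    t = tariffs if tariffs is not None else DEFAULT_TARIFFS
    bio = prescriptions[prescriptions["is_biologic"].astype(bool)].copy()
    bio["cost_gbp"] = [
        float(t.get(name, t.get(mol, 0.0)))
        for name, mol in zip(bio["drug_name"], bio["molecule"])
    ]
    return bio


def _sd(x: pd.Series) -> float:
    return float(x.std(ddof=1)) if len(x) > 1 else 0.0


def summarize(encounters: pd.DataFrame, prescriptions: pd.DataFrame,
              cohort: pd.DataFrame,
              grouping: Sequence[str] = ("diagnosis_group", "status",
                                         "care_type"),
              observations: Optional[pd.DataFrame] = None,
              params: Optional[ActivityParams] = None,
              tariffs: Optional[Dict[str, float]] = None,
              include_zero_patients: bool = True) -> pd.DataFrame:
    """Mean/SD of per-patient visits, length of stay, cost and biologic cost
    within every cell of ``grouping`` (any subset of diagnosis_group, status,
    age_band, care_type).

    When status is a grouping key, ``observations`` and ``params`` are
    required and both encounters and biologic prescriptions are labelled by
    patient-period status; a patient belongs to a status cell if they have at
    least one period of that status. ``include_zero_patients=False`` restricts
    the *visit-count* mean/SD to patients with at least one visit in the cell
    (cost means always include zeros).
    """
    keys = [k for k in grouping if k in GROUPING_KEYS]
    by_status = "status" in keys
    if by_status and (observations is None or params is None):
        raise ValueError("grouping by status requires observations and params")

    enc = encounters
    bio = price_biologic_prescriptions(prescriptions, tariffs)
    if by_status:
        if "status" not in enc.columns:
            enc, _ = attach_status(enc, observations, params)
        bio, _ = attach_status(bio, observations, params)

    base = cohort[["patient_id", "diagnosis_group", "age_band"]].copy()
    if by_status:
        pstat = observations[["patient_id", "status"]].drop_duplicates()
        base = base.merge(pstat, on="patient_id")
    if "care_type" in keys:
        base = base.merge(pd.DataFrame({"care_type": list(CARE_TYPES)}),
                          how="cross")

    join = ["patient_id"] + [k for k in ("status", "care_type") if k in keys]
    enc = enc[enc["patient_id"].isin(set(cohort["patient_id"]))]
    agg = enc.groupby(join).agg(
        visits=("date", "size"),
        los=("length_of_stay_days", "sum"),
        cost=("cost_gbp", "sum"),
    ).reset_index()
    per_patient = base.merge(agg, on=join, how="left")
    for c in ("visits", "los", "cost"):
        per_patient[c] = per_patient[c].fillna(0.0)

    bio_join = ["patient_id"] + (["status"] if by_status else [])
    bio = bio[bio["patient_id"].isin(set(cohort["patient_id"]))]
    bio_agg = bio.groupby(bio_join)["cost_gbp"].sum().rename("biologic_cost")
    per_patient = per_patient.merge(bio_agg.reset_index(), on=bio_join,
                                    how="left")
    per_patient["biologic_cost"] = per_patient["biologic_cost"].fillna(0.0)

    rows = []
    for cell_keys, cell in per_patient.groupby(keys, sort=True):
        if not isinstance(cell_keys, tuple):
            cell_keys = (cell_keys,)
        if cell["visits"].sum() == 0 and cell["biologic_cost"].sum() == 0:
            continue  # nothing observed in this cell: row omitted
        visits = cell["visits"]
        if not include_zero_patients:
            visits = visits[visits > 0]
        row = dict(zip(keys, cell_keys))
        row["n_patients"] = len(cell)
        row["visits_mean"] = float(visits.mean()) if len(visits) else 0.0
        row["visits_sd"] = _sd(visits)
        for name, col in (("los", "los"), ("cost", "cost"),
                          ("biologic_cost", "biologic_cost")):
            row[f"{name}_mean"] = float(cell[col].mean())
            row[f"{name}_sd"] = _sd(cell[col])
        rows.append(row)
    return pd.DataFrame(rows)


def total_cost(care_type_totals: Iterable[float],
               biologic_cost: float = 0.0) -> float:
    """One patient's grand total: care-setting cost totals plus biologics."""
    return float(np.sum(list(care_type_totals))) + float(biologic_cost)


def per_patient_totals(encounters: pd.DataFrame, prescriptions: pd.DataFrame,
                       cohort: pd.DataFrame,
                       tariffs: Optional[Dict[str, float]] = None
                       ) -> pd.DataFrame:
    """Per-patient cost totals per care type, biologic cost, and grand total
    (zero-encounter cohort members included as zeros)."""
    enc = encounters[encounters["patient_id"].isin(set(cohort["patient_id"]))]
    wide = (enc.pivot_table(index="patient_id", columns="care_type",
                            values="cost_gbp", aggfunc="sum", fill_value=0.0)
            .reindex(columns=list(CARE_TYPES), fill_value=0.0))
    wide = wide.reindex(cohort["patient_id"]).fillna(0.0)

    bio = price_biologic_prescriptions(prescriptions, tariffs)
    bio = bio[bio["patient_id"].isin(set(cohort["patient_id"]))]
    bio_total = bio.groupby("patient_id")["cost_gbp"].sum()
    wide["biologic_cost_gbp"] = bio_total.reindex(wide.index).fillna(0.0)
    wide["total_cost_gbp"] = wide.sum(axis=1)
    return wide.reset_index()
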