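"""First-biologic classification: drug category and initiation timing.

The first biologic prescription per patient (biosimilars counting as their
originator molecule's category) is classified *early* when it falls within
the early window (91 days, a deterministic reading of "3 months") after any
index event, and *late* otherwise. Under the strict second-event rule
(default), a start preceded by two or more therapy events within its own
12-month assessment period is late even when inside the early window.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .activity import period_of
from .config import ActivityParams, BiologicTimingRules

logger = logging.getLogger(__name__)

EPISODE_COLUMNS = [
    "patient_id",
    "first_biologic_date",
    "drug_name",
    "molecule",
    "category",
    "timing",
    "anchor_index_event_date",
]


def first_biologic(prescriptions: pd.DataFrame) -> pd.DataFrame:
    """Earliest biologic prescription per patient (no biologic → no row)."""
    bio = prescriptions[prescriptions["is_biologic"].astype(bool)]
    if len(bio) == 0:
        return pd.DataFrame(columns=["patient_id", "first_biologic_date",
                                     "drug_name", "molecule", "category"])
    bio = bio.sort_values(["patient_id", "date", "drug_name"], kind="stable")
    first = bio.groupby("patient_id", as_index=False).first()
    return pd.DataFrame({
        "patient_id": first["patient_id"],
        "first_biologic_date": pd.to_datetime(first["date"]),
        "drug_name": first["drug_name"],
        "molecule": first["molecule"],
        "category": first["drug_class"],
    })


def classify_timing(first_biologic_date, observations: pd.DataFrame,
                    events: pd.DataFrame, params: ActivityParams,
                    rules: Optional[BiologicTimingRules] = None) -> dict:
    """Early/late classification of one patient's first biologic.

    ``observations`` and ``events`` are that patient's rows. The anchor index
    event is the latest index event on/before the biologic date, or — when
    none precede it — the earliest one after it (timing is then late). A
    patient with no index event at all is late, with a logged anomaly.
    """
    rules = rules or BiologicTimingRules()
    bio_date = pd.Timestamp(first_biologic_date)

    idx_dates = pd.to_datetime(
        observations.loc[observations["status"] == "active",
                         "index_event_date"]
    ).dropna().sort_values()

    if len(idx_dates) == 0:
        if len(events) == 0:
            logger.warning(
                "biologic start with no therapy events at all for patient %s",
                observations["patient_id"].iloc[0] if len(observations)
                else "<unknown>",
            )
        return {"timing": "late", "anchor_index_event_date": pd.NaT}

    before = idx_dates[idx_dates <= bio_date]
    anchor = before.iloc[-1] if len(before) else idx_dates.iloc[0]

    deltas = (bio_date - idx_dates).dt.days
    within = ((deltas >= 0) & (deltas <= rules.early_window_days)).any()

    if within and rules.strict_second_event and len(events):
        bio_period = period_of(pd.Series([bio_date]), params).iloc[0]
        if not np.isnan(bio_period):
            ev_dates = pd.to_datetime(events["date"])
            ev_periods = period_of(events["date"], params)
            n_prior = int(((ev_periods == bio_period)
                           & (ev_dates < bio_date)).sum())
            if n_prior >= 2:
                within = False

    return {"timing": "early" if within else "late",
            "anchor_index_event_date": anchor}


def build_episodes(prescriptions: pd.DataFrame, observations: pd.DataFrame,
                   events: pd.DataFrame, params: ActivityParams,
                   rules: Optional[BiologicTimingRules] = None
                   ) -> pd.DataFrame:
    """First-biologic episodes with timing for every treated patient."""
    rules = rules or BiologicTimingRules()
    firsts = first_biologic(prescriptions)
    rows = []
    for _, ep in firsts.iterrows():
        pid = ep["patient_id"]
        obs = observations[observations["patient_id"] == pid]
        ev = events[events["patient_id"] == pid]
        timing = classify_timing(ep["first_biologic_date"], obs, ev, params,
                                 rules)
        rows.append({**ep.to_dict(), **timing})
    return pd.DataFrame(rows, columns=EPISODE_COLUMNS)


def timing_summary(episodes: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Treated/early/late counts and percentages, per diagnosis group and
    overall (percentages rounded half-up; early + late = treated)."""
    from .report import percentage

    merged = episodes.merge(
        cohort[["patient_id", "diagnosis_group"]], on="patient_id", how="inner"
    )
    rows = []
    groups = [(g, sub) for g, sub in merged.groupby("diagnosis_group",
                                                    sort=True)]
    groups.append(("overall", merged))
    for label, sub in groups:
        n = len(sub)
        n_early = int((sub["timing"] == "early").sum())
        n_late = n - n_early
        rows.append({
            "diagnosis_group": label,
            "n_treated": n,
            "n_early": n_early,
            "n_late": n_late,
            "early_pct": percentage(n_early, n) if n else 0,
            "late_pct": percentage(n_late, n) if n else 0,
        })
    return pd.DataFrame(rows, columns=["diagnosis_group", "n_treated",
                                       "n_early", "n_late", "early_pct",
                                       "late_pct"])
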