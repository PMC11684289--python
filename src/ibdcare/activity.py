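"""Assessment periods and active/remission classification.

Follow-up is cut into fixed 12-month periods anchored at the study start (so
every patient contributes exactly ``n_periods`` observations, including any
pre-diagnosis periods, which — containing no events — classify as remission).
A patient-period is *active* when it holds more than ``active_event_cutoff``
therapy events, *remission* otherwise; the first event of an active period is
its *index event*. Status is recorded as changed/unchanged between successive
periods.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np
import pandas as pd

from .config import ActivityParams
from .report import percentage

OBSERVATION_COLUMNS = [
    "patient_id",
    "period_index",
    "period_start",
    "period_end",
    "event_count",
    "status",
    "index_event_date",
    "status_changed_from_previous",
]


def build_periods(params: ActivityParams) -> List[Tuple[int, pd.Timestamp, pd.Timestamp]]:
    """Contiguous half-open [start, end) periods, 1-based indices."""
    anchor = pd.Timestamp(params.anchor)
    edges = [
        anchor + pd.DateOffset(months=params.period_months * i)
        for i in range(params.n_periods + 1)
    ]
    return [(i + 1, edges[i], edges[i + 1]) for i in range(params.n_periods)]


def period_of(dates: pd.Series, params: ActivityParams) -> pd.Series:
    """1-based period index for each date; NaN outside the grid (half-open)."""
    periods = build_periods(params)
    edges = pd.DatetimeIndex([p[1] for p in periods] + [periods[-1][2]])
    idx = edges.searchsorted(pd.to_datetime(dates).to_numpy(), side="right")
    out = pd.Series(idx, index=dates.index, dtype="float64")
    out[(out < 1) | (out > params.n_periods)] = np.nan
    return out


def classify_period(event_dates, params: ActivityParams,
                    period_index: int) -> dict:
    """Classify one patient-period from the dates of its events."""
    dates = pd.to_datetime(pd.Series(list(event_dates), dtype="datetime64[ns]"))
    n = len(dates)
    active = n > params.active_event_cutoff
    return {
        "period_index": period_index,
        "event_count": n,
        "status": "active" if active else "remission",
        "index_event_date": dates.min() if active else pd.NaT,
    }


def classify_all(events: pd.DataFrame, cohort: pd.DataFrame,
                 params: ActivityParams) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per patient-period activity observations plus a per-group summary.

    Every cohort member contributes exactly ``params.n_periods`` rows; events
    outside the period grid are ignored. The summary gives, per diagnosis
    group, total observations, remission observations, and remission percent
    (rounded half-up to an integer).
    """
    periods = build_periods(params)
    grid = pd.MultiIndex.from_product(
        [cohort["patient_id"], [p[0] for p in periods]],
        names=["patient_id", "period_index"],
    )

    ev = events[events["patient_id"].isin(set(cohort["patient_id"]))].copy()
    if len(ev):
        ev["period_index"] = period_of(ev["date"], params)
        ev = ev.dropna(subset=["period_index"])
        ev["period_index"] = ev["period_index"].astype(int)
        counts = ev.groupby(["patient_id", "period_index"])["date"].agg(
            ["count", "min"]
        )
    else:
        counts = pd.DataFrame(columns=["count", "min"])

    obs = counts.reindex(grid)
    obs["count"] = pd.to_numeric(obs["count"]).fillna(0).astype(int)
    obs = obs.rename(columns={"count": "event_count", "min": "index_event_date"})
    obs = obs.reset_index()
    obs["status"] = np.where(
        obs["event_count"] > params.active_event_cutoff, "active", "remission"
    )
    obs.loc[obs["status"] != "active", "index_event_date"] = pd.NaT
    obs["index_event_date"] = pd.to_datetime(obs["index_event_date"])

    pmap = {p[0]: (p[1], p[2]) for p in periods}
    obs["period_start"] = obs["period_index"].map(lambda i: pmap[i][0])
    obs["period_end"] = obs["period_index"].map(lambda i: pmap[i][1])

    obs = obs.sort_values(["patient_id", "period_index"]).reset_index(drop=True)
    prev = obs.groupby("patient_id")["status"].shift()
    changed = obs["status"] != prev
    obs["status_changed_from_previous"] = changed.where(prev.notna(), other=pd.NA)

    obs = obs[OBSERVATION_COLUMNS]

    merged = obs.merge(
        cohort[["patient_id", "diagnosis_group"]], on="patient_id", how="left"
    )
    rows = []
    for group, sub in merged.groupby("diagnosis_group", sort=True):
        n_obs = len(sub)
        n_rem = int((sub["status"] == "remission").sum())
        rows.append(
            {
                "diagnosis_group": group,
                "n_observations": n_obs,
                "n_remission": n_rem,
                "n_active": n_obs - n_rem,
                "remission_pct": percentage(n_rem, n_obs),
            }
        )
    summary = pd.DataFrame(
        rows,
        columns=[
            "diagnosis_group",
            "n_observations",
            "n_remission",
            "n_active",
            "remission_pct",
        ],
    )
    return obs, summary


def recovery_rate(observations: pd.DataFrame, truth: pd.DataFrame) -> float:
    """Fraction of patient-periods whose classified status matches the latent
    truth of a simulated dataset."""
    merged = observations.merge(
        truth, on=["patient_id", "period_index"], suffixes=("", "_truth")
    )
    if not len(merged):
        raise ValueError("no overlapping patient-periods between observations and truth")
    return float((merged["status"] == merged["status_truth"]).mean())
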