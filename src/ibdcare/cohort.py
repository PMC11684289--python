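"""Cohort selection: incident, adult, biologic-naive IBD patients.

Inclusion requires the earliest IBD diagnosis code to fall inside the
half-open study window. Exclusions, applied in a fixed order so each dropped
patient gets exactly one reason, are: under-age at diagnosis, non-incident
diagnosis, biologic exposure before diagnosis, and bowel resection before the
first biologic (or before diagnosis for never-treated patients). Patients
coded for both ulcerative colitis and Crohn's disease form the
``IBD_undefined`` group.
"""

from __future__ import annotations

import datetime as dt
import warnings
from typing import Optional, Tuple

import numpy as np
import pandas as pd

ADULT_AGE = 18  # inclusive at diagnosis; printed age ranges start at 18
AGE_BAND_SPLIT = 60

EXCLUSION_REASONS = (
    "under_age",
    "not_incident_in_window",
    "prior_biologic",
    "prior_resection",
)

COHORT_COLUMNS = [
    "patient_id",
    "diagnosis_group",
    "diagnosis_date",
    "age_at_diagnosis",
    "age_band",
    "sex",
]


class NotACandidateError(ValueError):
    """Patient has no IBD diagnosis code at all."""


def assign_diagnosis(first_uc_code_date, first_cd_code_date) -> str:
    """UC-only codes → UC; CD-only → CD; both → IBD_undefined (regardless of
    code order or gap); neither → error."""
    has_uc = pd.notna(first_uc_code_date)
    has_cd = pd.notna(first_cd_code_date)
    if has_uc and has_cd:
        return "IBD_undefined"
    if has_uc:
        return "UC"
    if has_cd:
        return "CD"
    raise NotACandidateError("patient has no UC or CD diagnosis code")


def _age_years(birth_date, at_date) -> int:
    """Completed years of age, calendar-exact."""
    b, d = pd.Timestamp(birth_date), pd.Timestamp(at_date)
    years = d.year - b.year
    if (d.month, d.day) < (b.month, b.day):
        years -= 1
    return int(years)


def select_cohort(patients: pd.DataFrame, prescriptions: pd.DataFrame,
                  window: Tuple[dt.date, dt.date],
                  biologic_lookback_days: Optional[int] = None
                  ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Apply inclusion/exclusion rules; return (cohort, exclusion log).

    ``window`` is half-open [start, end). ``biologic_lookback_days`` limits
    how far before diagnosis biologic exposure is screened (None = all
    available history). Prescriptions with unknown patient_id are ignored
    with a warning. Every input patient lands in exactly one of the two
    outputs; patients with no diagnosis code are excluded with reason
    ``no_ibd_code``.
    """
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    if end <= start:
        raise ValueError("window: end must be after start")

    known = set(patients["patient_id"])
    orphans = set(prescriptions["patient_id"]) - known
    if orphans:
        warnings.warn(
            f"ignoring prescriptions for {len(orphans)} unknown patient_id(s)",
            stacklevel=2,
        )
        prescriptions = prescriptions[prescriptions["patient_id"].isin(known)]

    bio = prescriptions[prescriptions["is_biologic"].astype(bool)]
    first_bio = bio.groupby("patient_id")["date"].min()

    members, exclusions = [], []
    for _, row in patients.iterrows():
        pid = row["patient_id"]
        try:
            group = assign_diagnosis(
                row["first_uc_code_date"], row["first_cd_code_date"]
            )
        except NotACandidateError:
            exclusions.append({"patient_id": pid, "reason": "no_ibd_code"})
            continue
        diagnosis_date = min(
            d for d in (row["first_uc_code_date"], row["first_cd_code_date"])
            if pd.notna(d)
        )
        diagnosis_date = pd.Timestamp(diagnosis_date)
        age = _age_years(row["birth_date"], diagnosis_date)

        reason = None
        if age < ADULT_AGE:
            reason = "under_age"
        elif not (start <= diagnosis_date < end):
            reason = "not_incident_in_window"
        else:
            bio_date = first_bio.get(pid, pd.NaT)
            screen_from = (
                diagnosis_date - pd.Timedelta(days=biologic_lookback_days)
                if biologic_lookback_days is not None else pd.Timestamp.min
            )
            if pd.notna(bio_date) and screen_from <= bio_date < diagnosis_date:
                reason = "prior_biologic"
            else:
                resection = row["resection_date"]
                cutoff = bio_date if pd.notna(bio_date) else diagnosis_date
                if pd.notna(resection) and pd.Timestamp(resection) < cutoff:
                    reason = "prior_resection"

        if reason is not None:
            exclusions.append({"patient_id": pid, "reason": reason})
            continue
        members.append(
            {
                "patient_id": pid,
                "diagnosis_group": group,
                "diagnosis_date": diagnosis_date,
                "age_at_diagnosis": age,
                "age_band": "18-59" if age < AGE_BAND_SPLIT else "60+",
                "sex": row["sex"],
            }
        )

    cohort = pd.DataFrame(members, columns=COHORT_COLUMNS)
    exclusion_log = pd.DataFrame(exclusions, columns=["patient_id", "reason"])
    return cohort, exclusion_log


def baseline_status(cohort: pd.DataFrame,
                    observations: pd.DataFrame) -> pd.DataFrame:
    """Each cohort member's status in the first assessment period."""
    first = observations[observations["period_index"] == 1]
    merged = cohort[["patient_id"]].merge(
        first[["patient_id", "status"]], on="patient_id", how="left"
    )
    if merged["status"].isna().any():
        missing = merged.loc[merged["status"].isna(), "patient_id"].tolist()
        raise ValueError(
            f"no first-period observation for patient(s) {missing[:5]}"
        )
    return merged.rename(columns={"status": "baseline_status"})
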