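"""Therapy-event detection from date-ordered prescription streams.

A therapy event is one of five treatment-change signals used as a proxy for
disease activity:

``new_non_biologic``
    a prescription that starts a course of a non-biologic drug (first-ever
    use of the molecule, or re-initiation after a gap of at least
    ``new_course_gap_days``);
``dose_escalation``
    a within-course prescription of a molecule at a strictly higher dose than
    the immediately preceding prescription of that molecule;
``class_addition``
    a course-starting prescription of one drug class while a *different*
    class is ongoing (dispensed within ``ongoing_window_days`` before);
``new_biologic``
    a course-starting biologic prescription with no other biologic molecule
    as the current therapy;
``biologic_change``
    a biologic prescription of a different molecule than the patient's
    current biologic — excluding originator/biosimilar switches of the same
    molecule, which are never events.

Each prescription row emits at most one event; when several rules match, the
priority is biologic_change > new_biologic > dose_escalation > class_addition
> new_non_biologic. Repeat dispensings at the same or a lower dose within an
ongoing course, and dose de-escalations, emit nothing.
"""

from __future__ import annotations

from typing import List, Optional

import pandas as pd

from .config import EventRules
from .vocabulary import DrugVocabulary, VocabularyError

EVENT_TYPES = (
    "new_non_biologic",
    "dose_escalation",
    "class_addition",
    "new_biologic",
    "biologic_change",
)

EVENT_COLUMNS = [
    "patient_id",
    "date",
    "event_type",
    "drug_name",
    "molecule",
    "drug_class",
    "prescription_index",
]


class _MoleculeState:
    __slots__ = ("last_date", "last_dose", "dose_unit")

    def __init__(self, last_date, last_dose, dose_unit):
        self.last_date = last_date
        self.last_dose = last_dose
        self.dose_unit = dose_unit


def _empty_events() -> pd.DataFrame:
    df = pd.DataFrame(columns=EVENT_COLUMNS)
    df["date"] = pd.to_datetime(df["date"])
    return df


def detect_events(prescriptions: pd.DataFrame,
                  rules: Optional[EventRules] = None) -> pd.DataFrame:
    """Detect therapy events in one patient's prescription stream.

    ``prescriptions`` must be sorted by (date, drug_name) and carry the
    classified columns (drug_class, molecule, is_biologic, is_biosimilar).
    Same-day duplicate rows of one drug are deduplicated (first kept). Mixed
    dose units within one molecule are a vocabulary error, not a guess.
    """
    rules = rules or EventRules()
    if len(prescriptions) == 0:
        return _empty_events()
    if prescriptions["patient_id"].nunique() > 1:
        raise ValueError("detect_events: stream spans more than one patient")

    dates = pd.to_datetime(prescriptions["date"])
    order_key = list(zip(dates, prescriptions["drug_name"]))
    if any(order_key[i] > order_key[i + 1] for i in range(len(order_key) - 1)):
        raise ValueError("detect_events: input must be sorted by (date, drug_name)")

    unknown = set(prescriptions["drug_class"]) - set(
        ("five_asa", "corticosteroid", "immunomodulator", "small_molecule",
         "anti_tnf", "non_anti_tnf", "unclassified")
    )
    if unknown:
        bad = prescriptions[prescriptions["drug_class"].isin(unknown)]
        raise VocabularyError(
            f"unknown drug_class for drug(s) {sorted(set(bad['drug_name']))}"
        )

    stream = prescriptions.copy()
    stream["date"] = dates
    stream = stream.drop_duplicates(subset=["date", "drug_name"], keep="first")

    molecule_state: dict[str, _MoleculeState] = {}
    class_last_date: dict[str, pd.Timestamp] = {}
    current_biologic: Optional[str] = None  # molecule of most recent biologic

    events: List[dict] = []
    for idx, row in stream.iterrows():
        date = row["date"]
        molecule = row["molecule"]
        drug_class = row["drug_class"]
        dose = float(row["dose_value"])

        state = molecule_state.get(molecule)
        if state is not None and state.dose_unit != row["dose_unit"]:
            raise VocabularyError(
                f"mixed dose units for {molecule!r}: "
                f"{state.dose_unit!r} vs {row['dose_unit']!r}"
            )
        gap = None if state is None else (date - state.last_date).days
        initiating = state is None or gap >= rules.new_course_gap_days

        event_type = None
        if row["is_biologic"]:
            if current_biologic is None:
                event_type = "new_biologic"
            elif molecule != current_biologic:
                # a genuine switch of molecule; originator<->biosimilar of the
                # same molecule never reaches this branch
                event_type = "biologic_change"
            elif initiating:
                event_type = "new_biologic"  # re-initiation after a gap
            elif dose > state.last_dose:
                event_type = "dose_escalation"
            current_biologic = molecule
        else:
            if initiating:
                ongoing_other = any(
                    cls != drug_class
                    and (date - last).days <= rules.ongoing_window_days
                    for cls, last in class_last_date.items()
                )
                event_type = ("class_addition" if ongoing_other
                              else "new_non_biologic")
            elif dose > state.last_dose:
                event_type = "dose_escalation"

        if event_type is not None:
            events.append(
                {
                    "patient_id": row["patient_id"],
                    "date": date,
                    "event_type": event_type,
                    "drug_name": row["drug_name"],
                    "molecule": molecule,
                    "drug_class": drug_class,
                    "prescription_index": idx,
                }
            )

        molecule_state[molecule] = _MoleculeState(date, dose, row["dose_unit"])
        class_last_date[drug_class] = date

    if not events:
        return _empty_events()
    return pd.DataFrame(events, columns=EVENT_COLUMNS)


def detect_events_all(prescriptions: pd.DataFrame,
                      rules: Optional[EventRules] = None) -> pd.DataFrame:
    """Detect events for every patient in a multi-patient table."""
    rules = rules or EventRules()
    if len(prescriptions) == 0:
        return _empty_events()
    parts = []
    ordered = prescriptions.sort_values(
        ["patient_id", "date", "drug_name"], kind="stable"
    )
    for _, stream in ordered.groupby("patient_id", sort=True):
        parts.append(detect_events(stream.reset_index(drop=True), rules))
    out = pd.concat(parts, ignore_index=True)
    return out


def classify_prescriptions(prescriptions: pd.DataFrame,
                           vocabulary: Optional[DrugVocabulary] = None,
                           strict: bool = True) -> pd.DataFrame:
    """Attach drug_class/molecule/is_biologic/is_biosimilar columns from the
    vocabulary, given raw rows with at least drug_name."""
    vocab = vocabulary or DrugVocabulary.default()
    out = prescriptions.copy()
    entries = [vocab.classify(name, strict=strict)
               for name in out["drug_name"]]
    out["drug_class"] = [e.drug_class for e in entries]
    out["molecule"] = [e.molecule for e in entries]
    out["is_biologic"] = [e.is_biologic for e in entries]
    out["is_biosimilar"] = [e.is_biosimilar for e in entries]
    return out
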