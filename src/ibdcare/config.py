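"""Configuration models for the simulation and analysis pipeline.

All tunable knobs live in pydantic models so that invalid configurations fail
loudly, naming the offending field, before any table is generated or analysed.
"""

from __future__ import annotations

import datetime as dt
from typing import Dict

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

CARE_TYPES = (
    "elective_inpatient",
    "non_elective_inpatient",
    "outpatient",
    "primary_care",
    "community",
)
INPATIENT_TYPES = ("elective_inpatient", "non_elective_inpatient")

DIAGNOSIS_GROUPS = ("UC", "CD", "IBD_undefined")

DRUG_CLASSES = (
    "five_asa",
    "corticosteroid",
    "immunomodulator",
    "small_molecule",
    "anti_tnf",
    "non_anti_tnf",
)
BIOLOGIC_CLASSES = ("anti_tnf", "non_anti_tnf")


class ConfigurationError(ValueError):
    """Raised when a configuration value is invalid; names the field."""


class RateByStatus(BaseModel):
    """Expected encounters per 12-month assessment period, by latent status."""

    active: float = Field(ge=0)
    remission: float = Field(ge=0)


class CostParams(BaseModel):
    """Right-skewed (log-normal) per-encounter cost: arithmetic mean and
    log-scale sigma, GBP."""

    mean_gbp: float = Field(gt=0)
    sigma: float = Field(gt=0)


class SimulationConfig(BaseModel):
    """Parameters of the synthetic linked-EHR generator.

    The latent disease course is a two-state (active/remission) first-order
    chain over fixed 12-month assessment periods anchored at ``study_start``.
    Therapy-event-generating prescriptions are emitted Poisson per period at a
    status-dependent rate; encounters likewise per care type.
    """

    n_patients: int = Field(default=500, ge=0)
    study_start: dt.date = dt.date(2016, 3, 31)
    study_end: dt.date = dt.date(2020, 3, 31)

    # diagnosis-code mix: UC only / CD only / codes for both
    diag_mix: Dict[str, float] = Field(
        default_factory=lambda: {"UC": 0.76, "CD": 0.18, "both": 0.06}
    )

    p_active_initial: float = Field(default=0.35, ge=0, le=1)
    p_stay_active: float = Field(default=0.5, ge=0, le=1)
    p_stay_remission: float = Field(default=0.9, ge=0, le=1)

    event_rate_active: float = Field(default=5.0, ge=0)
    event_rate_remission: float = Field(default=0.5, ge=0)

    encounter_rate: Dict[str, RateByStatus] = Field(
        default_factory=lambda: {
            "elective_inpatient": RateByStatus(active=0.8, remission=0.55),
            "non_elective_inpatient": RateByStatus(active=0.55, remission=0.4),
            "outpatient": RateByStatus(active=2.2, remission=1.0),
            "primary_care": RateByStatus(active=8.0, remission=7.0),
            "community": RateByStatus(active=1.0, remission=0.7),
        }
    )
    cost_params: Dict[str, CostParams] = Field(
        default_factory=lambda: {
            "elective_inpatient": CostParams(mean_gbp=2500.0, sigma=0.8),
            "non_elective_inpatient": CostParams(mean_gbp=3000.0, sigma=0.8),
            "outpatient": CostParams(mean_gbp=150.0, sigma=0.5),
            "primary_care": CostParams(mean_gbp=39.0, sigma=0.3),
            "community": CostParams(mean_gbp=120.0, sigma=0.6),
        }
    )
    # mean inpatient length of stay (days) by latent status
    los_params: Dict[str, float] = Field(
        default_factory=lambda: {"active": 4.0, "remission": 3.0}
    )

    p_biologic: float = Field(default=0.05, ge=0, le=1)
    p_non_anti_tnf_first: float = Field(default=0.3, ge=0, le=1)
    p_biosimilar_switch: float = Field(default=0.25, ge=0, le=1)
    p_early_biologic: float = Field(default=0.4, ge=0, le=1)

    # exclusion-fixture probabilities
    p_prior_resection: float = Field(default=0.03, ge=0, le=1)
    p_prevalent_case: float = Field(default=0.05, ge=0, le=1)
    p_underage: float = Field(default=0.02, ge=0, le=1)

    pre_diagnosis_margin_days: int = Field(default=0, ge=0)
    maintenance_repeat_days: int = Field(default=28, ge=1)

    seed: int = 0

    @field_validator("diag_mix")
    @classmethod
    def _diag_mix_valid(cls, v: Dict[str, float]) -> Dict[str, float]:
        if set(v) != {"UC", "CD", "both"}:
            raise ValueError("diag_mix: keys must be exactly {UC, CD, both}")
        if any(p < 0 or p > 1 for p in v.values()):
            raise ValueError("diag_mix: probabilities must lie in [0, 1]")
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("diag_mix: probabilities must sum to 1")
        return v

    @field_validator("encounter_rate", "cost_params")
    @classmethod
    def _care_type_keys(cls, v, info):
        unknown = set(v) - set(CARE_TYPES)
        if unknown:
            raise ValueError(f"{info.field_name}: unknown care types {sorted(unknown)}")
        missing = set(CARE_TYPES) - set(v)
        if missing:
            raise ValueError(f"{info.field_name}: missing care types {sorted(missing)}")
        return v

    @field_validator("los_params")
    @classmethod
    def _los_valid(cls, v: Dict[str, float]) -> Dict[str, float]:
        if set(v) != {"active", "remission"}:
            raise ValueError("los_params: keys must be exactly {active, remission}")
        if any(m < 1 for m in v.values()):
            raise ValueError("los_params: mean length of stay must be >= 1 day")
        return v

    @model_validator(mode="after")
    def _cross_field(self) -> "SimulationConfig":
        if self.study_end <= self.study_start:
            raise ValueError("study_end: must be after study_start")
        if self.event_rate_active <= self.event_rate_remission:
            raise ValueError(
                "event_rate_active: must exceed event_rate_remission"
            )
        return self

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except Exception as exc:  # surface pydantic detail with our error type
            raise ConfigurationError(str(exc)) from exc


class EventRules(BaseModel):
    """Knobs of the therapy-event detector.

    new_course_gap_days: a prescription of a molecule re-initiates a course
        (and so counts as a "new prescription") when at least this many days
        have passed since the molecule was last dispensed.
    ongoing_window_days: a drug class counts as ongoing if any prescription of
        it fell within this many days before the row under evaluation.
    strict_vocabulary: unknown drug names raise instead of being bucketed as
        "unclassified".
    """

    new_course_gap_days: int = Field(default=90, ge=1)
    ongoing_window_days: int = Field(default=60, ge=1)
    strict_vocabulary: bool = True

    @classmethod
    def from_yaml(cls, path) -> "EventRules":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except Exception as exc:
            raise ConfigurationError(str(exc)) from exc


class ActivityParams(BaseModel):
    """Assessment-period grid and the active-disease cutoff.

    A patient-period is active when its therapy-event count strictly exceeds
    ``active_event_cutoff`` (default 2, i.e. "more than two events"), remission
    otherwise. Periods are ``period_months`` long, anchored at ``anchor``.
    """

    period_months: int = Field(default=12, gt=0)
    active_event_cutoff: int = Field(default=2, ge=0)
    n_periods: int = Field(default=4, gt=0)
    anchor: dt.date = dt.date(2016, 3, 31)

    @classmethod
    def from_yaml(cls, path) -> "ActivityParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except Exception as exc:
            raise ConfigurationError(str(exc)) from exc


class BiologicTimingRules(BaseModel):
    """Early/late biologic-initiation classification.

    early_window_days: a start within this many days (inclusive) after an
        index event is "early" (3 months read as 91 days for determinism).
    strict_second_event: when True, a start preceded by two or more therapy
        events within its own 12-month assessment period is late even if it
        falls inside the early window of that period's index event.
    """

    early_window_days: int = Field(default=91, ge=0)
    strict_second_event: bool = True
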