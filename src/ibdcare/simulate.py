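"""Synthetic linked-EHR generator with a known latent disease course.

Each patient carries a hidden active/remission state following a first-order
two-state chain over the fixed 12-month assessment periods. Active periods
emit therapy-event-generating prescriptions at a higher Poisson rate than
remission periods; encounter counts, costs (log-normal, right-skewed, GBP)
and inpatient lengths of stay are likewise status-dependent. The generator is
built so that every "event prescription" triggers exactly one detector event
(a course initiation at base dose, or a within-course dose escalation),
while maintenance repeats at unchanged dose and same-molecule biosimilar
switches trigger none — so detected per-period event counts reproduce the
configured rates and the latent truth is recoverable downstream.

A configurable fraction of patients carry exclusion features (under-age,
diagnosis before the study window, prior bowel resection) to exercise cohort
selection.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np
import pandas as pd

from .config import CARE_TYPES, INPATIENT_TYPES, ActivityParams, SimulationConfig
from .activity import build_periods
from .vocabulary import DrugVocabulary

# non-biologic pool: molecule -> (drug_class, base dose in mg)
_CONVENTIONAL = {
    "mesalazine": ("five_asa", 800.0),
    "sulfasalazine": ("five_asa", 500.0),
    "balsalazide": ("five_asa", 750.0),
    "prednisolone": ("corticosteroid", 20.0),
    "budesonide": ("corticosteroid", 9.0),
    "hydrocortisone": ("corticosteroid", 100.0),
    "azathioprine": ("immunomodulator", 50.0),
    "mercaptopurine": ("immunomodulator", 25.0),
    "methotrexate": ("immunomodulator", 15.0),
    "tofacitinib": ("small_molecule", 10.0),
}

_ANTI_TNF = ("infliximab", "adalimumab")
_NON_ANTI_TNF = ("vedolizumab", "ustekinumab")
_BIOLOGIC_DOSE = {"infliximab": 400.0, "adalimumab": 40.0,
                  "vedolizumab": 300.0, "ustekinumab": 90.0}
_BIOLOGIC_REPEAT_DAYS = 56
_ESCALATION_FACTOR = 1.5

PATIENT_COLUMNS = ["patient_id", "birth_date", "sex", "first_uc_code_date",
                   "first_cd_code_date", "resection_date", "registration_date"]
PRESCRIPTION_COLUMNS = ["patient_id", "date", "drug_name", "drug_class",
                        "molecule", "dose_value", "dose_unit", "is_biologic",
                        "is_biosimilar"]
ENCOUNTER_COLUMNS = ["patient_id", "date", "care_type", "length_of_stay_days",
                     "cost_gbp"]
TRUTH_COLUMNS = ["patient_id", "period_index", "status"]


def activity_params_for(config: SimulationConfig) -> ActivityParams:
    """Assessment-period grid implied by the study window (12-month periods
    anchored at the study start)."""
    months = ((config.study_end.year - config.study_start.year) * 12
              + (config.study_end.month - config.study_start.month))
    n_periods = max(1, months // 12)
    return ActivityParams(anchor=config.study_start, n_periods=n_periods)


def _empty_tables() -> Dict[str, pd.DataFrame]:
    tables = {
        "patients": pd.DataFrame(columns=PATIENT_COLUMNS),
        "prescriptions": pd.DataFrame(columns=PRESCRIPTION_COLUMNS),
        "encounters": pd.DataFrame(columns=ENCOUNTER_COLUMNS),
        "truth": pd.DataFrame(columns=TRUTH_COLUMNS),
    }
    for name, date_cols in (
        ("patients", PATIENT_COLUMNS[1:2] + PATIENT_COLUMNS[3:]),
        ("prescriptions", ["date"]),
        ("encounters", ["date"]),
    ):
        for c in date_cols:
            if c != "sex":
                tables[name][c] = pd.to_datetime(tables[name][c])
    return tables


def _latent_sequence(rng, config, n_periods: int, first_period: int) -> List[str]:
    """Two-state chain from the diagnosis period on; earlier periods are
    pre-diagnosis and carry no disease activity."""
    statuses = ["remission"] * (first_period - 1)
    state = "active" if rng.random() < config.p_active_initial else "remission"
    statuses.append(state)
    for _ in range(first_period, n_periods):
        stay = (config.p_stay_active if state == "active"
                else config.p_stay_remission)
        if rng.random() >= stay:
            state = "remission" if state == "active" else "active"
        statuses.append(state)
    return statuses


def _sample_days(rng, lo: pd.Timestamp, hi: pd.Timestamp, k: int,
                 distinct: bool) -> List[pd.Timestamp]:
    span = (hi - lo).days
    if span <= 0 or k <= 0:
        return []
    if distinct:
        k = min(k, span)
        offsets = rng.choice(span, size=k, replace=False)
    else:
        offsets = rng.integers(0, span, size=k)
    return sorted(lo + pd.Timedelta(days=int(o)) for o in offsets)


def generate(config: SimulationConfig) -> Dict[str, pd.DataFrame]:
    """Generate linked patients/prescriptions/encounters tables plus the
    latent truth; deterministic for a given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    params = activity_params_for(config)
    periods = build_periods(params)
    grid_end = periods[-1][2]
    start = pd.Timestamp(config.study_start)
    window_days = (pd.Timestamp(config.study_end) - start).days

    vocab = DrugVocabulary.default()
    patients, prescriptions, encounters, truth = [], [], [], []

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        underage = rng.random() < config.p_underage
        prevalent = rng.random() < config.p_prevalent_case
        prior_resection = rng.random() < config.p_prior_resection

        if prevalent:
            diagnosis = start - pd.Timedelta(days=int(rng.integers(1, 451)))
        else:
            diagnosis = start + pd.Timedelta(days=int(rng.integers(0, window_days)))

        age = int(rng.integers(14, 18) if underage else rng.integers(18, 91))
        birth_date = (diagnosis - pd.DateOffset(years=age)
                      - pd.Timedelta(days=int(rng.integers(0, 365))))
        registration = diagnosis - pd.Timedelta(days=int(rng.integers(365, 3651)))
        resection = (diagnosis - pd.Timedelta(days=int(rng.integers(30, 1001)))
                     if prior_resection else pd.NaT)
        sex = "M" if rng.random() < 0.5 else "F"

        u = rng.random()
        if u < config.diag_mix["UC"]:
            uc_date, cd_date = diagnosis, pd.NaT
        elif u < config.diag_mix["UC"] + config.diag_mix["CD"]:
            uc_date, cd_date = pd.NaT, diagnosis
        else:
            second = diagnosis + pd.Timedelta(days=int(rng.integers(30, 366)))
            if rng.random() < 0.5:
                uc_date, cd_date = diagnosis, second
            else:
                uc_date, cd_date = second, diagnosis

        patients.append({
            "patient_id": pid, "birth_date": birth_date, "sex": sex,
            "first_uc_code_date": uc_date, "first_cd_code_date": cd_date,
            "resection_date": resection, "registration_date": registration,
        })

        first_period = 1
        if not prevalent:
            for pidx, pstart, pend in periods:
                if pstart <= diagnosis < pend:
                    first_period = pidx
                    break
        statuses = _latent_sequence(rng, config, params.n_periods, first_period)
        for pidx, status in enumerate(statuses, start=1):
            truth.append({"patient_id": pid, "period_index": pidx,
                          "status": status})

        # -------- therapy-event prescriptions --------
        pool = list(_CONVENTIONAL)
        rng.shuffle(pool)
        event_plan: List[tuple] = []  # (date, molecule)
        counter = 0
        for pidx, pstart, pend in periods:
            if pidx < first_period:
                continue
            status = statuses[pidx - 1]
            rate = (config.event_rate_active if status == "active"
                    else config.event_rate_remission)
            k = int(rng.poisson(rate))
            lo = max(pstart, diagnosis)
            for date in _sample_days(rng, lo, pend, k, distinct=True):
                event_plan.append((date, pool[counter % len(pool)]))
                counter += 1
        event_plan.sort(key=lambda t: t[0])

        next_same: List[pd.Timestamp] = []
        last_seen: Dict[str, pd.Timestamp] = {}
        for date, mol in reversed(event_plan):
            next_same.insert(0, last_seen.get(mol, grid_end))
            last_seen[mol] = date

        state: Dict[str, tuple] = {}  # molecule -> (last_date, current dose)
        for (date, mol), nxt in zip(event_plan, next_same):
            cls, base = _CONVENTIONAL[mol]
            prev = state.get(mol)
            if prev is None or (date - prev[0]).days >= 90:
                dose = base  # new course
            else:
                dose = prev[1] * _ESCALATION_FACTOR  # dose escalation
            prescriptions.append({
                "patient_id": pid, "date": date, "drug_name": mol,
                "drug_class": cls, "molecule": mol, "dose_value": dose,
                "dose_unit": "mg", "is_biologic": False,
                "is_biosimilar": False,
            })
            last = date
            for j in range(1, int(rng.integers(0, 3)) + 1):
                rdate = date + pd.Timedelta(days=j * config.maintenance_repeat_days)
                if rdate >= min(nxt, grid_end):
                    break
                prescriptions.append({
                    "patient_id": pid, "date": rdate, "drug_name": mol,
                    "drug_class": cls, "molecule": mol, "dose_value": dose,
                    "dose_unit": "mg", "is_biologic": False,
                    "is_biosimilar": False,
                })
                last = rdate
            state[mol] = (last, dose)

        # -------- first biologic and its maintenance stream --------
        if rng.random() < config.p_biologic:
            active_periods = [pidx for pidx, s in enumerate(statuses, start=1)
                              if s == "active" and pidx >= first_period]
            if active_periods:
                apidx = active_periods[0]
                pstart, pend = periods[apidx - 1][1], periods[apidx - 1][2]
                in_period = [d for d, _ in event_plan if pstart <= d < pend]
                anchor = min(in_period) if in_period else max(pstart, diagnosis)
            else:
                anchor = diagnosis if not prevalent else start
            # early-intent starts are placed shortly after the index event so
            # that most survive the strict second-event rule downstream
            if rng.random() < config.p_early_biologic:
                delta = int(rng.integers(0, 46))
            else:
                delta = int(rng.integers(92, 331))
            bio_date = anchor + pd.Timedelta(days=delta)
            if bio_date >= grid_end:
                bio_date = grid_end - pd.Timedelta(days=1)
            if rng.random() < config.p_non_anti_tnf_first:
                mol = _NON_ANTI_TNF[int(rng.integers(0, len(_NON_ANTI_TNF)))]
            else:
                mol = _ANTI_TNF[int(rng.integers(0, len(_ANTI_TNF)))]
            entry = vocab.classify(mol)
            dose = _BIOLOGIC_DOSE[mol]
            repeat_dates = []
            d = bio_date
            while True:
                d = d + pd.Timedelta(days=_BIOLOGIC_REPEAT_DAYS)
                if d >= grid_end:
                    break
                repeat_dates.append(d)
            switch_from = None
            has_biosimilar = f"{mol}-biosimilar" in vocab
            if (has_biosimilar and repeat_dates
                    and rng.random() < config.p_biosimilar_switch):
                switch_from = int(rng.integers(0, len(repeat_dates)))
            for k, d in enumerate([bio_date] + repeat_dates):
                biosim = switch_from is not None and k - 1 >= switch_from
                prescriptions.append({
                    "patient_id": pid, "date": d,
                    "drug_name": f"{mol}-biosimilar" if biosim else mol,
                    "drug_class": entry.drug_class, "molecule": mol,
                    "dose_value": dose, "dose_unit": "mg",
                    "is_biologic": True, "is_biosimilar": biosim,
                })

        # -------- encounters --------
        for pidx, pstart, pend in periods:
            if pidx < first_period:
                continue
            status = statuses[pidx - 1]
            lo = max(pstart, diagnosis)
            for care_type in CARE_TYPES:
                lam = getattr(config.encounter_rate[care_type], status)
                n = int(rng.poisson(lam))
                dates = _sample_days(rng, lo, pend, n, distinct=False)
                cp = config.cost_params[care_type]
                mu = np.log(cp.mean_gbp) - cp.sigma ** 2 / 2
                for d in dates:
                    cost = round(float(rng.lognormal(mu, cp.sigma)), 2)
                    if care_type in INPATIENT_TYPES:
                        los = 1 + int(rng.poisson(config.los_params[status] - 1))
                    else:
                        los = 0
                    encounters.append({
                        "patient_id": pid, "date": d, "care_type": care_type,
                        "length_of_stay_days": los, "cost_gbp": cost,
                    })

    if not patients:
        return _empty_tables()

    tables = {
        "patients": pd.DataFrame(patients, columns=PATIENT_COLUMNS),
        "prescriptions": pd.DataFrame(prescriptions,
                                      columns=PRESCRIPTION_COLUMNS),
        "encounters": pd.DataFrame(encounters, columns=ENCOUNTER_COLUMNS),
        "truth": pd.DataFrame(truth, columns=TRUTH_COLUMNS),
    }
    tables["prescriptions"] = tables["prescriptions"].sort_values(
        ["patient_id", "date", "drug_name"], kind="stable"
    ).reset_index(drop=True)
    tables["encounters"] = tables["encounters"].sort_values(
        ["patient_id", "date", "care_type"], kind="stable"
    ).reset_index(drop=True)
    for name in ("patients", "prescriptions", "encounters"):
        for col in tables[name].columns:
            if col.endswith("date") or col == "date":
                tables[name][col] = pd.to_datetime(tables[name][col])
    return tables
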