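"""Cost aggregation: status labelling, per-patient means, conservation."""

import numpy as np
import pandas as pd
import pytest

from ibdcare import (
    ActivityParams,
    SimulationConfig,
    attach_status,
    generate,
    per_patient_totals,
    run_pipeline,
    summarize,
    total_cost,
)
from ibdcare.costs import DEFAULT_TARIFFS, price_biologic_prescriptions

PARAMS = ActivityParams()


def _enc(rows):
    """rows: (patient_id, date, care_type, los, cost)."""
    return pd.DataFrame(
        [
            {"patient_id": p, "date": pd.Timestamp(d), "care_type": ct,
             "length_of_stay_days": los, "cost_gbp": float(c)}
            for p, d, ct, los, c in rows
        ]
    )


def _obs(rows):
    return pd.DataFrame(
        [{"patient_id": p, "period_index": i, "status": s} for p, i, s in rows]
    )


def _cohort(pids, group="UC", band="18-59"):
    return pd.DataFrame({
        "patient_id": pids,
        "diagnosis_group": [group] * len(pids),
        "age_band": [band] * len(pids),
    })


def _no_rx():
    return pd.DataFrame(columns=["patient_id", "date", "drug_name",
                                 "molecule", "is_biologic"])


class TestAttachStatus:
    def test_status_join_and_boundary(self):
        enc = _enc([
            ("a", "2016-06-01", "outpatient", 0, 100),   # period 1
            ("a", "2017-03-31", "outpatient", 0, 100),   # boundary -> period 2
            ("a", "2021-01-01", "outpatient", 0, 100),   # after the grid
        ])
        obs = _obs([("a", 1, "active"), ("a", 2, "remission"),
                    ("a", 3, "remission"), ("a", 4, "remission")])
        labelled, dropped = attach_status(enc, obs, PARAMS)
        assert dropped == 1
        assert list(labelled["status"]) == ["active", "remission"]
        assert list(labelled["period_index"]) == [1, 2]


class TestSummarize:
    def test_hand_arithmetic_mean_sd(self):
        enc = _enc([("a", "2016-06-01", "outpatient", 0, 100),
                    ("b", "2016-07-01", "outpatient", 0, 300)])
        out = summarize(enc, _no_rx(), _cohort(["a", "b"]),
                        grouping=("diagnosis_group",))
        row = out.iloc[0]
        assert row["n_patients"] == 2
        assert row["cost_mean"] == 200.0
        assert row["cost_sd"] == pytest.approx(141.4214, abs=1e-3)

    def test_single_patient_sd_zero(self):
        enc = _enc([("a", "2016-06-01", "outpatient", 0, 100)])
        out = summarize(enc, _no_rx(), _cohort(["a"]),
                        grouping=("diagnosis_group",))
        assert out.iloc[0]["cost_sd"] == 0.0

    def test_zero_encounter_patient_contributes_zero(self):
        enc = _enc([("a", "2016-06-01", "outpatient", 0, 100)])
        out = summarize(enc, _no_rx(), _cohort(["a", "b"]),
                        grouping=("diagnosis_group",))
        assert out.iloc[0]["cost_mean"] == 50.0

    def test_unused_care_types_absent(self):
        enc = _enc([("a", "2016-06-01", "outpatient", 0, 100)])
        out = summarize(enc, _no_rx(), _cohort(["a"]),
                        grouping=("care_type",))
        assert list(out["care_type"]) == ["outpatient"]

    def test_include_zero_patients_switch(self):
        enc = _enc([("a", "2016-06-01", "outpatient", 0, 100)])
        cohort = _cohort(["a", "b"])
        with_zeros = summarize(enc, _no_rx(), cohort,
                               grouping=("diagnosis_group",))
        without = summarize(enc, _no_rx(), cohort,
                            grouping=("diagnosis_group",),
                            include_zero_patients=False)
        assert with_zeros.iloc[0]["visits_mean"] == 0.5
        assert without.iloc[0]["visits_mean"] == 1.0
        # cost means keep the zero patients either way
        assert without.iloc[0]["cost_mean"] == 50.0


class TestTariffs:
    def test_pricing_falls_back_to_molecule(self):
        rx = pd.DataFrame({
            "patient_id": ["a", "a"],
            "drug_name": ["infliximab", "golimumab-biosim-x"],
            "molecule": ["infliximab", "golimumab"],
            "is_biologic": [True, True],
        })
        priced = price_biologic_prescriptions(rx)
        assert priced["cost_gbp"].tolist() == [
            DEFAULT_TARIFFS["infliximab"], DEFAULT_TARIFFS["golimumab"],
        ]

    def test_custom_tariff_overrides(self):
        rx = pd.DataFrame({"patient_id": ["a"], "drug_name": ["infliximab"],
                           "molecule": ["infliximab"], "is_biologic": [True]})
        priced = price_biologic_prescriptions(rx, {"infliximab": 99.0})
        assert priced["cost_gbp"].iloc[0] == 99.0


class TestTotals:
    def test_grand_total_addition(self):
        assert total_cost([500, 250, 0, 125, 0], 1000) == 1875.0
        assert total_cost([0, 0, 0, 0, 0], 0) == 0.0

    def test_per_patient_totals_match_brute_force(self, small_dataset,
                                                  small_results):
        cohort = small_results["cohort"]
        enc = small_dataset["encounters"]
        rx = small_dataset["prescriptions"]
        totals = per_patient_totals(enc, rx, cohort).set_index("patient_id")
        priced = price_biologic_prescriptions(rx)
        for pid in cohort["patient_id"].iloc[:50]:
            expected = (
                enc.loc[enc["patient_id"] == pid, "cost_gbp"].sum()
                + priced.loc[priced["patient_id"] == pid, "cost_gbp"].sum()
            )
            assert totals.loc[pid, "total_cost_gbp"] == pytest.approx(
                expected, abs=1e-6
            )

    def test_status_split_conserves_pooled_total(self, small_dataset,
                                                 small_results):
        """Active-labelled plus remission-labelled encounter costs equal each
        patient's all-encounter cost inside the period grid."""
        obs = small_results["observations"]
        cohort = small_results["cohort"]
        enc = small_dataset["encounters"]
        enc = enc[enc["patient_id"].isin(set(cohort["patient_id"]))]
        labelled, dropped = attach_status(enc, obs, PARAMS)
        assert dropped == 0
        split = labelled.groupby(["patient_id", "status"])["cost_gbp"].sum()
        pooled = enc.groupby("patient_id")["cost_gbp"].sum()
        recombined = split.groupby("patient_id").sum()
        assert np.allclose(
            recombined.reindex(pooled.index, fill_value=0.0), pooled,
            atol=1e-6,
        )

    def test_summary_non_negative(self, small_results):
        rs = small_results["resource_summary"]
        value_cols = [c for c in rs.columns if c.endswith(("_mean", "_sd"))]
        assert (rs[value_cols] >= 0).all().all()
        assert (rs["n_patients"] > 0).all()
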