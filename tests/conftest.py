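from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ibdcare import SimulationConfig, generate, run_pipeline
from ibdcare.vocabulary import DrugVocabulary

VOCAB = DrugVocabulary.default()


def rx_rows(patient_id, *rows):
    """Build a classified prescription frame from (date, drug_name,
    dose_value) tuples, attributes filled from the default vocabulary."""
    records = []
    for date, drug_name, dose in rows:
        entry = VOCAB.classify(drug_name)
        records.append(
            {
                "patient_id": patient_id,
                "date": pd.Timestamp(date),
                "drug_name": drug_name,
                "drug_class": entry.drug_class,
                "molecule": entry.molecule,
                "dose_value": float(dose),
                "dose_unit": "mg",
                "is_biologic": entry.is_biologic,
                "is_biosimilar": entry.is_biosimilar,
            }
        )
    df = pd.DataFrame(records)
    return df.sort_values(["date", "drug_name"], kind="stable").reset_index(
        drop=True
    )


def random_stream(rng: np.random.Generator, max_rows: int = 8) -> pd.DataFrame:
    """A random sorted prescription stream over a small drug set."""
    names = ["mesalazine", "prednisolone", "azathioprine",
             "infliximab", "infliximab-biosimilar", "vedolizumab"]
    n = int(rng.integers(1, max_rows + 1))
    base = pd.Timestamp("2017-01-01")
    rows = []
    for _ in range(n):
        name = names[int(rng.integers(0, len(names)))]
        rows.append((
            base + pd.Timedelta(days=int(rng.integers(0, 300))),
            name,
            float(rng.choice([10.0, 20.0, 40.0])),
        ))
    return rx_rows("PX", *rows)


@pytest.fixture(scope="session")
def small_dataset():
    return generate(SimulationConfig(n_patients=200, seed=7))


@pytest.fixture(scope="session")
def small_results(small_dataset):
    return run_pipeline(small_dataset)
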