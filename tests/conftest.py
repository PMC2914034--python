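import numpy as np
import pandas as pd
import pytest

from medchurn.panel_io import SCHEMA_COLUMNS, from_dataframe
from medchurn.synthetic_data import default_config, generate_dataset


def make_manual_panel(sequences: dict, T: int = 5, **overrides) -> pd.DataFrame:
    """Build a minimal schema-complete long frame from per-person columns.

    ``sequences`` maps person_id -> dict of column -> list-of-length-T (for
    round-varying columns) or scalar (for baseline columns).  Unspecified
    columns get benign defaults.
    """
    defaults = {
        "medicaid": 1, "employed": 0, "healthy": 1, "income": 1.0,
        "er_visits": 0, "outpatient_visits": 0, "inpatient_discharges": 0,
        "rx_fills": 0, "age": 40, "male": 0, "married": 0, "high_school": 1,
        "white": 1, "family_size": 2, "chronic_count": 0,
    }
    rows = []
    for pid, cols in sequences.items():
        for t in range(1, T + 1):
            row = {"person_id": pid, "round": t}
            for col in SCHEMA_COLUMNS[2:]:
                val = cols.get(col, overrides.get(col, defaults[col]))
                row[col] = val[t - 1] if isinstance(val, (list, tuple, np.ndarray)) else val
            rows.append(row)
    return pd.DataFrame(rows, columns=SCHEMA_COLUMNS)


@pytest.fixture(scope="session")
def small_dataset():
    """Synthetic default panel, 120 persons x 6 rounds."""
    config = default_config(n_persons=120, seed=7)
    dataset, _ = generate_dataset(config)
    return dataset


@pytest.fixture(scope="session")
def medium_dataset():
    """Synthetic default panel, 600 persons x 6 rounds (fit-quality tests)."""
    config = default_config(n_persons=600, seed=21)
    dataset, _ = generate_dataset(config)
    return dataset
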