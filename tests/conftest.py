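import math

import pandas as pd
import pytest

import mdiaquant as mq


def make_row(**overrides):
    """One internal-form report row with sensible defaults."""
    row = {
        "run_id": "run1",
        "protein_group": "P1",
        "genes": "G1",
        "precursor_id": "(Dimethyl-n-0)PEPTIDER2",
        "modified_sequence": "(Dimethyl-n-0)PEPTIDER",
        "stripped_sequence": "PEPTIDER",
        "charge": 2,
        "channel": 0,
        "q_value": 0.001,
        "global_pg_q_value": 0.001,
        "pg_q_value": 0.01,
        "lib_pg_q_value": 0.001,
        "channel_q_value": 0.001,
        "translated_q_value": 0.001,
        "ms1_area": 1000.0,
        "precursor_translated": 500.0,
        "precursor_normalised": 500.0,
        "fragment_quant_raw": [100.0, 200.0, 300.0],
    }
    row.update(overrides)
    return row


def make_report(rows):
    return pd.DataFrame([make_row(**r) for r in rows])


@pytest.fixture
def two_channel_design():
    return mq.ExperimentDesign(
        pd.DataFrame(
            {
                "run": ["run1", "run1"],
                "channel": [0, 4],
                "role": ["reference", "target"],
                "sample_name": ["run1_ref", "run1_d4"],
            }
        )
    )


@pytest.fixture
def nan():
    return math.nan
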