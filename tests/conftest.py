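import numpy as np
import pandas as pd
import pytest

from meddsurvey.ingest import AMOUNT_COLUMNS, RECALL_COLUMNS
from meddsurvey.survey import SurveyDesign


def make_recall_frame(rows: list[dict]) -> pd.DataFrame:
    """Build a recall-day table from sparse row dicts (unset amounts = 0)."""
    out = []
    for row in rows:
        full = {col: 0.0 for col in AMOUNT_COLUMNS}
        full.update(row)
        out.append(full)
    return pd.DataFrame(out)[RECALL_COLUMNS]


@pytest.fixture
def two_day_recalls():
    """One participant, two recall days with distinct amounts."""
    return make_recall_frame(
        [
            {"SEQN": 1, "DAY": 1, "FPED_WHOLEGRAIN_G": 100.0, "ENERGY_KCAL": 1800.0},
            {"SEQN": 1, "DAY": 2, "FPED_WHOLEGRAIN_G": 200.0, "ENERGY_KCAL": 2200.0},
        ]
    )


@pytest.fixture
def srs_design():
    """Equal weights, one stratum, each record its own PSU: classical i.i.d."""

    def _make(n):
        return SurveyDesign(np.ones(n), np.arange(n), np.ones(n))

    return _make


@pytest.fixture
def clustered_design():
    """8 strata x 3 PSUs x 20 records with variable weights (seeded)."""
    rng = np.random.default_rng(1234)
    S, P, m = 8, 3, 20
    strata = np.repeat(np.arange(S), P * m)
    psu = np.tile(np.repeat(np.arange(P), m), S)
    w = np.exp(rng.normal(0, 0.4, S * P * m))
    return SurveyDesign(strata, psu, w), rng
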