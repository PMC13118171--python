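"""Shared fixtures: a small hierarchy and toy surveys."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from prevmap.survey_data import AreaHierarchy, load_survey


@pytest.fixture
def hierarchy():
    """2 Admin-1 areas (A, B), 4 Admin-2 areas (A: a1, a2; B: b1, b2)."""
    return AreaHierarchy.from_table(
        pd.DataFrame(
            {"admin2": ["a1", "a2", "b1", "b2"], "admin1": ["A", "A", "B", "B"]}
        )
    )


@pytest.fixture
def toy_rows():
    return pd.DataFrame(
        {
            "cluster": [1, 1, 2, 2],
            "stratum": ["A:U", "A:U", "A:R", "A:R"],
            "admin1": ["A", "A", "A", "A"],
            "admin2": ["a1", "a1", "a2", "a2"],
            "urban": [True, True, False, False],
            "y": [1, 0, 1, 0],
            "weight": [1.0, 1.0, 1.0, 1.0],
        }
    )


@pytest.fixture
def toy_dataset(toy_rows, hierarchy):
    return load_survey(toy_rows, hierarchy)


def make_survey(records, hierarchy):
    """Build a SurveyDataset from (cluster, stratum, admin1, admin2, urban, y, w) tuples."""
    df = pd.DataFrame(
        records, columns=["cluster", "stratum", "admin1", "admin2", "urban", "y", "weight"]
    )
    return load_survey(df, hierarchy)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
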