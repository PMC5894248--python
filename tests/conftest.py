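import numpy as np
import pandas as pd
import pytest

from ehrphewas import fixture_map_path, load_phecode_map


@pytest.fixture(scope="session")
def pmap():
    return load_phecode_map(fixture_map_path())


def make_events(rows):
    """rows: (subject_id, code, vocabulary, date, setting) tuples."""
    return pd.DataFrame(
        rows, columns=["subject_id", "code", "vocabulary", "date", "setting"]
    )


def make_labs(rows):
    """rows: (subject_id, titer) pairs; dates are arbitrary."""
    return pd.DataFrame(
        [
            {"subject_id": s, "test": "ANA", "date": "2010-01-01", "titer": t}
            for s, t in rows
        ],
        columns=["subject_id", "test", "date", "titer"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
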