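import numpy as np
import pandas as pd
import pytest

from hierkit import (
    SyntheticConfig,
    WinLoseMatrix,
    generate_dataset,
    make_event_table,
)


def simple_roster(ids):
    n = len(ids)
    return pd.DataFrame(
        {
            "id": list(ids),
            "sex": ["F"] * n,
            "age_class": ["adult"] * n,
            "forearm_mm": [53.0] * n,
            "mass_g": [36.0] * n,
            "population": ["tole"] * n,
            "is_mother": [False] * n,
        }
    )


def events_frame(rows):
    """rows: list of (winner, loser) or (winner, loser, type)."""
    recs = []
    for k, row in enumerate(rows):
        w, l = row[0], row[1]
        typ = row[2] if len(row) > 2 else "ci"
        recs.append(
            {"night": 1, "time_min": float(k), "winner": w, "loser": l, "type": typ}
        )
    return pd.DataFrame(recs)


def table_from(rows, ids=None):
    df = events_frame(rows)
    if ids is None:
        ids = sorted(set(df["winner"]) | set(df["loser"]))
    return make_event_table(df, simple_roster(ids))


@pytest.fixture
def toy_table():
    return table_from([("A", "B"), ("A", "B"), ("C", "A")])


@pytest.fixture
def linear_matrix():
    # perfect linear order A > B > C > D, every dyad decided
    W = np.zeros((4, 4), dtype=int)
    for i in range(4):
        for j in range(i + 1, 4):
            W[i, j] = 3
    return WinLoseMatrix(["A", "B", "C", "D"], W)


@pytest.fixture
def cyclic_matrix():
    W = np.array([[0, 2, 0], [0, 0, 2], [2, 0, 0]])
    return WinLoseMatrix(["A", "B", "C"], W)


@pytest.fixture(scope="session")
def default_dataset():
    return generate_dataset(SyntheticConfig(), seed=11)


def flat_config(n=30, n_events=1000, beta=0.0, **kw):
    """All-adult-female colony used in simulation studies."""
    return SyntheticConfig(
        n_adult_females=n, n_young_females=0, n_young_males=0,
        n_events=n_events, beta=beta, **kw,
    )
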