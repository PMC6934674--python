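import datetime as dt

import pandas as pd
import pytest

from socioscan.scan_data import Individual, Roster, SCAN_COLUMNS, INTERACTION_COLUMNS
from socioscan.simulate import SimConfig, generate


def make_scans(rows):
    """rows: (scan_id, date_iso, period, individual, context, state, neighbours)"""
    recs = [
        (sid, dt.date.fromisoformat(d), per, ind, ctx, st, frozenset(nb))
        for sid, d, per, ind, ctx, st, nb in rows
    ]
    return pd.DataFrame(recs, columns=SCAN_COLUMNS)


def make_interactions(rows):
    """rows: (scan_id, actor, recipient, context)"""
    return pd.DataFrame(rows, columns=INTERACTION_COLUMNS)


@pytest.fixture
def tiny_roster():
    return Roster(
        [
            Individual("A", "adult", "female"),
            Individual("B", "adult", "male"),
            Individual("C", "juvenile", "male"),
            Individual("D", "juvenile", "female"),
        ]
    )


@pytest.fixture(scope="session")
def sim_data():
    """One default synthetic dataset shared across tests."""
    return generate(SimConfig(seed=7))


@pytest.fixture(scope="session")
def sim_analysis(sim_data):
    from socioscan.scan_data import apply_exclusions

    scans, interactions, roster = apply_exclusions(sim_data.scans, sim_data.interactions, sim_data.roster)
    return scans, interactions, roster
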