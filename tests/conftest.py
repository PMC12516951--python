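"""Shared fixtures: a small hand-made dataset and one session-scoped
default synthetic scenario (generation is deterministic, so sharing it
across test modules is safe)."""

import numpy as np
import pandas as pd
import pytest

from sewerflow.io_formats import METADATA_COLUMNS, CountTable
from sewerflow.synthetic_data import CommunityScenario, simulate_habitats


def make_meta(rows):
    """rows: list of (sample_id, habitat) or dicts with overrides."""
    records = []
    for r in rows:
        if isinstance(r, dict):
            rec = r
        else:
            sid, hab = r
            rec = {"sample_id": sid, "habitat": hab}
        full = {
            "location_id": "L00",
            "wwtp": "AAW" if rec.get("habitat") in ("IWW", "AS") else "none",
            "timestamp": pd.Timestamp("2023-01-01"),
            "sewer_type": "combined",
            "replicate_group": rec["sample_id"],
        }
        full.update(rec)
        records.append(full)
    return pd.DataFrame(records)[list(METADATA_COLUMNS)]


@pytest.fixture
def tiny_table():
    counts = pd.DataFrame(
        [[3, 0], [1, 5]], index=["s1", "s2"], columns=["f1", "f2"]
    )
    return CountTable(counts)


@pytest.fixture(scope="session")
def default_scenario():
    return CommunityScenario()


@pytest.fixture(scope="session")
def simulated(default_scenario):
    """(table, meta, taxonomy, truth) for the default seeded scenario."""
    table, meta, tax = simulate_habitats(default_scenario)
    truth = default_scenario.planted_truth()
    return table, meta, tax, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230921)
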