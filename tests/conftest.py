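"""Shared fixtures: synthetic cohorts and featurized molecule sets.

Everything is generated programmatically with fixed seeds; session scope keeps
the expensive featurization work shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pvtrigger import pharmacovigilance as pv
from pvtrigger.mol_features import featurize_table
from pvtrigger.synthetic import SimConfig, generate_molecule_set, generate_reports

TARGET_EVENT = "JUVENILE IDIOPATHIC ARTHRITIS"


def planted_config(**overrides) -> SimConfig:
    base = dict(
        n_reports=20000,
        drugs=[f"D{i:02d}" for i in range(10)],
        events=[TARGET_EVENT, "NAUSEA", "RASH", "HEADACHE"],
        background_rate=0.01,
        planted_signals={("D00", TARGET_EVENT): 10.0},
        tto_params={"D00": (60.0, 0.6)},
        dup_fraction=0.1,
        comed_fraction=0.2,
        seed=11,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def planted_reports() -> pd.DataFrame:
    return generate_reports(planted_config())


@pytest.fixture(scope="session")
def dedup_reports(planted_reports) -> pd.DataFrame:
    return pv.deduplicate(planted_reports)


@pytest.fixture(scope="session")
def mol120() -> pd.DataFrame:
    return generate_molecule_set(60, 60, seed=3)


@pytest.fixture(scope="session")
def mol120_features(mol120):
    des = featurize_table(mol120, "descriptors")
    graphs, idx = featurize_table(mol120, "graph")
    y = (mol120.assign(cid=mol120["cid"].astype(str)).set_index("cid")
         .loc[des.index, "label"].to_numpy())
    assert list(des.index) == list(idx)
    return {"descriptors": des, "graphs": graphs, "labels": y}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
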