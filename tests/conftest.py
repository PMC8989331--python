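import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import swinenet as sn

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    """A medium synthetic registry with defect-target holdings appended."""
    cfg = sn.SynthConfig(n_holdings=250, seed=11)
    return sn.generate_holdings(cfg)


@pytest.fixture(scope="session")
def industry_attrs(registry):
    industry = registry[
        registry["country"].eq("FR")
        & ~registry["overseas"]
        & registry["husbandry_activity"].isin(
            ["FA", "PW", "FI", "FF", "FPW", "PWF", "MU", "NU"]
        )
    ]
    return sn.build_attribute_table(industry)


@pytest.fixture(scope="session")
def truth_model():
    return sn.default_ground_truth()


@pytest.fixture(scope="session")
def trade_network(industry_attrs, truth_model):
    return sn.simulate_ergm_network(industry_attrs, truth_model, seed=21)


def make_events(rows):
    """Build an event DataFrame from (tid, kind, holding, date, cat, heads, seq)."""
    df = pd.DataFrame(
        rows,
        columns=[
            "transport_id", "event_kind", "holding_id", "date",
            "animal_category", "head_count", "sequence_index",
        ],
    )
    df["date"] = pd.to_datetime(df["date"])
    df["movement_kind"] = "commercial"
    return df


def make_holdings(ids, **overrides):
    n = len(ids)
    base = {
        "holding_id": ids,
        "owner_id": [f"O{i}" for i in range(n)],
        "x": np.linspace(0, 10, n),
        "y": np.zeros(n),
        "country": ["FR"] * n,
        "town": ["T"] * n,
        "production_type": ["standard"] * n,
        "husbandry_activity": ["FI"] * n,
        "species": ["pig"] * n,
        "outdoor": [False] * n,
        "cap_repro": [0] * n,
        "cap_postwean": [0] * n,
        "cap_fatten": [100] * n,
        "company_id": ["independent"] * n,
        "overseas": [False] * n,
        "insular": [False] * n,
        "record_date": ["2016-01-01"] * n,
    }
    base.update(overrides)
    df = pd.DataFrame(base)
    df["record_date"] = pd.to_datetime(df["record_date"])
    return df
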