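"""Cleaning cascade, deduplication and movement reconstruction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import swinenet as sn
from swinenet.ingest import (
    FormatError,
    apply_filters,
    activity_filter,
    consistency_filter,
    deduplicate_holdings,
    read_holdings,
    read_transport_log,
    reconstruct_movements,
)

from conftest import make_events, make_holdings


# ---------------------------------------------------------------- readers

def test_read_empty_file_with_header(tmp_path):
    path = tmp_path / "log.csv"
    pd.DataFrame(columns=sn.ingest.EVENT_COLUMNS).to_csv(path, index=False)
    df = read_transport_log(path)
    assert len(df) == 0


def test_read_missing_header_is_format_error(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("a,b,c\n1,2,3\n")
    with pytest.raises(FormatError):
        read_transport_log(path)
    with pytest.raises(FormatError):
        read_holdings(path)


def test_negative_head_count_flagged_not_dropped(tmp_path):
    ev = make_events([("T1", "loading", "A", "2019-07-01", "piglet", -5, 0)])
    path = tmp_path / "log.csv"
    ev.to_csv(path, index=False)
    df = read_transport_log(path)
    assert len(df) == 1 and df["_invalid"].iloc[0]


def test_write_read_round_trip(tmp_path, registry, trade_network):
    log, _ = sn.network_to_transport_log(trade_network, seed=1)
    hpath, lpath = tmp_path / "h.csv", tmp_path / "l.csv"
    sn.synth.write_holdings(registry, hpath)
    sn.synth.write_transport_log(log, lpath)
    h2 = read_holdings(hpath)
    l2 = read_transport_log(lpath)
    assert len(h2) == len(registry)
    assert len(l2) == len(log)
    assert set(zip(l2["transport_id"], l2["event_kind"], l2["holding_id"])) == set(
        zip(log["transport_id"], log["event_kind"], log["holding_id"])
    )


# ---------------------------------------------------------- deduplication

def test_same_id_keeps_most_recent_record():
    df = make_holdings(["A", "A"], record_date=["2017-01-01", "2019-01-01"],
                       cap_fatten=[50, 80])
    out = deduplicate_holdings(df)
    assert len(out) == 1
    assert out["cap_fatten"].iloc[0] == 80


def test_single_record_unchanged():
    df = make_holdings(["A"])
    out = deduplicate_holdings(df)
    assert len(out) == 1 and out["holding_id"].iloc[0] == "A"


def test_same_owner_merge_respects_500m_threshold():
    near = make_holdings(["A", "B"], owner_id=["O", "O"], x=[0.0, 0.4], y=[0.0, 0.0],
                         record_date=["2017-01-01", "2018-01-01"])
    out = deduplicate_holdings(near)
    assert len(out) == 1 and out["holding_id"].iloc[0] == "A"  # earliest id kept

    far = make_holdings(["A", "B"], owner_id=["O", "O"], x=[0.0, 0.6], y=[0.0, 0.0])
    out = deduplicate_holdings(far)
    assert len(out) == 2


# -------------------------------------------------------------- filters

def test_missing_transport_id_removed_and_tallied():
    holdings = make_holdings(["A", "B"])
    ev = make_events(
        [
            ("", "loading", "A", "2019-07-01", "piglet", 10, 0),
            ("T2", "loading", "A", "2019-07-01", "piglet", 10, 0),
            ("T2", "unloading", "B", "2019-07-01", "piglet", 10, 1),
        ]
    )
    kept, tally = apply_filters(ev, holdings)
    assert tally.reasons["missing_id"] == 1
    assert len(kept) == 2


def test_clean_log_passes_untouched():
    holdings = make_holdings(["A", "B"])
    ev = make_events(
        [
            ("T1", "loading", "A", "2019-07-01", "piglet", 10, 0),
            ("T1", "unloading", "B", "2019-07-02", "piglet", 10, 1),
        ]
    )
    kept, tally = apply_filters(ev, holdings)
    assert len(kept) == len(ev)
    assert tally.total_removed == 0


def test_filter_cascade_idempotent(registry, trade_network):
    rates = {"missing_id": 0.08, "international": 0.05, "overseas": 0.04,
             "unmatched_event": 0.05, "animal_removal": 0.04}
    log, _ = sn.network_to_transport_log(
        trade_network, defect_rates=rates, seed=13,
        foreign_ids=list(registry.loc[registry["country"] != "FR", "holding_id"]),
        overseas_ids=list(registry.loc[registry["overseas"], "holding_id"]),
    )
    once, t1 = apply_filters(log, registry)
    twice, t2 = apply_filters(once, registry)
    assert len(once) == len(twice)
    assert t2.total_removed == 0


def test_tally_conservation(registry, trade_network):
    rates = {"missing_id": 0.1, "direct_sale_or_unmarked": 0.05}
    log, _ = sn.network_to_transport_log(trade_network, defect_rates=rates, seed=14)
    kept, tally = apply_filters(log, registry)
    assert tally.input_count == tally.output_count + tally.total_removed


# ------------------------------------------------------- activity filter

def test_activity_filter_counts():
    holdings = make_holdings([f"H{i}" for i in range(100)])
    rows = []
    for i in range(40):
        rows.append((f"T{i}", "loading", f"H{i}", "2019-07-05", "piglet", 5, 0))
    ev = make_events(rows)
    active = activity_filter(holdings, ev, window=("2019-07-01", "2019-12-31"))
    assert len(active) == 40

    assert activity_filter(holdings, ev.iloc[0:0]) == set()


def test_single_unloading_makes_holding_active():
    holdings = make_holdings(["A"])
    ev = make_events([("T1", "unloading", "A", "2019-08-01", "sow", 2, 1)])
    assert activity_filter(holdings, ev) == {"A"}


# ---------------------------------------------------- consistency filter

def test_consistency_rules():
    holdings = make_holdings(["FAFARM", "NUFARM", "FIFARM", "X"],
                             husbandry_activity=["FA", "NU", "FI", "PW"],
                             production_type=["standard", "nucleus", "standard", "standard"],
                             cap_repro=[100, 100, 0, 0],
                             cap_postwean=[0, 200, 0, 300],
                             cap_fatten=[0, 0, 400, 0])
    attrs = sn.build_attribute_table(holdings)
    reg = holdings.merge(attrs["farm_type"], left_on="holding_id", right_index=True)
    movements = pd.DataFrame(
        {
            "origin_id": ["FAFARM", "NUFARM", "FIFARM", "X", "FAFARM", "FIFARM"],
            "dest_id": ["X"] * 6,
            "date": pd.to_datetime(["2019-07-01"] * 6),
            "animal_category": ["barrow", "sow", "piglet", "growing_pig",
                                "piglet", "growing_pig"],
            "head_count": [5] * 6,
        }
    )
    out, removed = consistency_filter(movements, reg)
    # barrow from FA and piglet from FI violate the rule table; sow from NU is
    # the canonical breeding-sector export and stays
    assert removed == 2
    assert len(out) == 4
    assert "NUFARM" in set(out["origin_id"])


# ------------------------------------------------- movement reconstruction

def test_minimal_pair_reconstruction():
    ev = make_events(
        [
            ("T1", "loading", "A", "2019-07-01", "piglet", 10, 0),
            ("T1", "unloading", "B", "2019-07-01", "piglet", 10, 1),
        ]
    )
    mov = reconstruct_movements(ev)
    assert len(mov) == 1
    assert (mov["origin_id"].iloc[0], mov["dest_id"].iloc[0]) == ("A", "B")


def test_sequence_not_starting_with_loading_is_dropped():
    ev = make_events(
        [
            ("T1", "unloading", "B", "2019-07-01", "piglet", 10, 0),
            ("T1", "loading", "A", "2019-07-01", "piglet", 10, 1),
        ]
    )
    assert len(reconstruct_movements(ev)) == 0


def test_multi_stop_pairing_product():
    ev = make_events(
        [
            ("T1", "loading", "A", "2019-07-01", "piglet", 10, 0),
            ("T1", "loading", "B", "2019-07-01", "piglet", 10, 1),
            ("T1", "unloading", "C", "2019-07-01", "piglet", 10, 2),
            ("T1", "unloading", "D", "2019-07-01", "piglet", 10, 3),
        ]
    )
    mov = reconstruct_movements(ev)
    got = set(zip(mov["origin_id"], mov["dest_id"]))
    assert got == {("A", "C"), ("A", "D"), ("B", "C"), ("B", "D")}


@given(
    st.lists(
        st.tuples(
            st.sampled_from(["loading", "unloading"]),
            st.sampled_from(["A", "B", "C"]),
            st.sampled_from(["piglet", "sow"]),
        ),
        min_size=1,
        max_size=8,
    )
)
def test_reconstruction_no_self_loops_no_category_mixing(seq):
    rows = [
        ("T1", kind, hid, "2019-07-01", cat, 5, i)
        for i, (kind, hid, cat) in enumerate(seq)
    ]
    mov = reconstruct_movements(make_events(rows))
    assert (mov["origin_id"] != mov["dest_id"]).all()
    # a movement of a category requires both event kinds for that category
    for cat in set(mov["animal_category"]):
        kinds = {kind for kind, _, c in seq if c == cat}
        assert kinds == {"loading", "unloading"}
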