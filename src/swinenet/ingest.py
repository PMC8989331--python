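"""Reading, cleaning and movement reconstruction for swine transport logs.

The raw material is two tables: a holdings registry (one row per declared pig
holding) and a transport log of ordered loading/unloading events.  National
movement databases of this kind are noisy — duplicated holding records,
international and overseas legs, records missing identifiers, orphan events —
so cleaning applies a fixed cascade of removal reasons with an auditable
per-reason tally, then reconstructs directed origin→destination movements
from the surviving loading/unloading pairs.

Tables are carried as pandas DataFrames with the column schemas below; the
CSV writers in :mod:`swinenet.synth` produce exactly these schemas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HOLDING_COLUMNS",
    "EVENT_COLUMNS",
    "MOVEMENT_COLUMNS",
    "FormatError",
    "FilterTally",
    "read_holdings",
    "read_transport_log",
    "deduplicate_holdings",
    "apply_filters",
    "activity_filter",
    "consistency_filter",
    "reconstruct_movements",
]

HOLDING_COLUMNS = [
    "holding_id", "owner_id", "x", "y", "country", "town",
    "production_type", "husbandry_activity", "species", "outdoor",
    "cap_repro", "cap_postwean", "cap_fatten", "company_id",
    "overseas", "insular", "record_date",
]

EVENT_COLUMNS = [
    "transport_id", "event_kind", "holding_id", "date", "animal_category",
    "head_count", "sequence_index", "movement_kind",
]

MOVEMENT_COLUMNS = ["origin_id", "dest_id", "date", "animal_category", "head_count"]

#: removal reasons of the cleaning cascade, in precedence order; each record
#: is removed (and tallied) under the first reason it matches.
FILTER_REASONS = [
    "outside_window",
    "international",
    "direct_sale_or_unmarked",
    "missing_id",
    "unregistered_holding",
    "animal_removal",
    "unmatched_event",
    "overseas",
]


class FormatError(ValueError):
    """Input file does not match the documented schema."""


@dataclass
class FilterTally:
    """Auditable record of how many events each cleaning reason removed."""

    reasons: dict = field(default_factory=dict)
    input_count: int = 0
    output_count: int = 0

    @property
    def total_removed(self) -> int:
        return sum(self.reasons.values())

    def to_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "output_count": self.output_count,
            "removed": dict(self.reasons),
        }


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{what} is missing required columns {missing}")


def read_holdings(path) -> pd.DataFrame:
    """Read a holdings registry CSV.

    Rows whose mandatory fields do not parse (empty holding id, negative
    capacity) are flagged in an ``_invalid`` column rather than dropped, so
    callers can audit them.
    """
    df = pd.read_csv(path, dtype={"holding_id": str, "owner_id": str,
                                  "company_id": str})
    _require_columns(df, HOLDING_COLUMNS, "holdings registry")
    df["record_date"] = pd.to_datetime(df["record_date"], errors="coerce")
    for cap in ("cap_repro", "cap_postwean", "cap_fatten"):
        df[cap] = pd.to_numeric(df[cap], errors="coerce")
    bad_id = df["holding_id"].isna() | (df["holding_id"].astype(str).str.len() == 0)
    bad_cap = (df[["cap_repro", "cap_postwean", "cap_fatten"]] < 0).any(axis=1)
    df["_invalid"] = bad_id | bad_cap
    df["outdoor"] = df["outdoor"].astype(bool)
    df["overseas"] = df["overseas"].astype(bool)
    df["insular"] = df["insular"].astype(bool)
    return df


def read_transport_log(path) -> pd.DataFrame:
    """Read a transport-log CSV of ordered loading/unloading events.

    Invalid rows (unknown event kind, non-positive head count, unparseable
    date) are flagged in ``_invalid``, not silently dropped.
    """
    df = pd.read_csv(path, dtype={"transport_id": str, "holding_id": str})
    _require_columns(df, EVENT_COLUMNS, "transport log")
    df["date"] = pd.to_datetime(df["date"], errors="coerce")
    df["head_count"] = pd.to_numeric(df["head_count"], errors="coerce")
    bad = (
        ~df["event_kind"].isin(["loading", "unloading"])
        | df["date"].isna()
        | ~(df["head_count"] > 0)
    )
    df["_invalid"] = bad
    return df


def _euclidean_km(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.hypot(a[0] - b[0], a[1] - b[1]))


def deduplicate_holdings(holdings: pd.DataFrame, radius_m: float = 500.0) -> pd.DataFrame:
    """Resolve duplicate registry rows.

    Two rules, applied in order:

    1. rows sharing a ``holding_id`` keep only the most recent ``record_date``;
    2. distinct holdings belonging to the same owner and lying within
       ``radius_m`` of each other are treated as one holding (sites further
       apart than the radius are genuinely different holdings, even under
       the same owner) and merged under the earliest-created id.
    """
    df = holdings.sort_values("record_date").drop_duplicates(
        subset="holding_id", keep="last"
    )
    radius_km = radius_m / 1000.0
    # union-find over same-owner pairs within the radius
    parent = {hid: hid for hid in df["holding_id"]}

    def find(h):
        while parent[h] != h:
            parent[h] = parent[parent[h]]
            h = parent[h]
        return h

    for _, grp in df.groupby("owner_id"):
        if len(grp) < 2 or grp[["x", "y"]].isna().any().any():
            continue
        ids = grp["holding_id"].to_numpy()
        xy = grp[["x", "y"]].to_numpy(dtype=float)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if _euclidean_km(xy[i], xy[j]) <= radius_km:
                    ri, rj = find(ids[i]), find(ids[j])
                    if ri != rj:
                        parent[rj] = ri
    # representative per cluster = earliest record_date (ties by id)
    cluster = df["holding_id"].map(find)
    reps = (
        df.assign(_cluster=cluster)
        .sort_values(["record_date", "holding_id"])
        .drop_duplicates(subset="_cluster", keep="first")
        .drop(columns="_cluster")
    )
    return reps.reset_index(drop=True)


def apply_filters(
    events: pd.DataFrame,
    holdings: pd.DataFrame,
    window: tuple | None = None,
    home_country: str = "FR",
) -> tuple[pd.DataFrame, FilterTally]:
    """Apply the cleaning cascade to the transport log.

    Reasons are applied as sequential passes in the fixed precedence order of
    :data:`FILTER_REASONS`; each event is removed and tallied at most once,
    under the first reason it matches.  The passes are:

    - ``outside_window``: event date outside the study window (if given);
    - ``international``: the referenced holding is registered abroad;
    - ``direct_sale_or_unmarked``: direct sales, household slaughter and
      unmarked animals;
    - ``missing_id``: missing transport or holding identification;
    - ``unregistered_holding``: holding id absent from the registry;
    - ``animal_removal``: removal of dead or missing animals;
    - ``unmatched_event``: the transport lacks at least one loading and one
      unloading among the surviving records;
    - ``overseas``: the holding lies in an overseas territory.
    """
    tally = FilterTally(input_count=len(events))
    reg = holdings.set_index("holding_id")
    country = reg["country"]
    overseas = reg["overseas"]
    df = events.copy()

    def remove(mask: pd.Series, reason: str) -> None:
        nonlocal df
        tally.reasons[reason] = int(mask.sum())
        df = df[~mask]

    if window is not None:
        start, end = pd.to_datetime(window[0]), pd.to_datetime(window[1])
        remove(~df["date"].between(start, end), "outside_window")
    else:
        tally.reasons["outside_window"] = 0

    known = df["holding_id"].isin(reg.index)
    ev_country = df["holding_id"].map(country)
    remove(known & (ev_country != home_country), "international")
    remove(
        df["movement_kind"].isin(["direct_sale", "household_slaughter", "unmarked"]),
        "direct_sale_or_unmarked",
    )
    missing = (
        df["transport_id"].isna()
        | (df["transport_id"].astype(str).str.len() == 0)
        | df["holding_id"].isna()
        | (df["holding_id"].astype(str).str.len() == 0)
    )
    remove(missing, "missing_id")
    remove(~df["holding_id"].isin(reg.index), "unregistered_holding")
    remove(df["movement_kind"] == "removal", "animal_removal")
    kinds = df.groupby("transport_id")["event_kind"].agg(frozenset)
    complete = df["transport_id"].map(kinds).apply(
        lambda s: "loading" in s and "unloading" in s
    )
    remove(~complete, "unmatched_event")
    remove(df["holding_id"].map(overseas).fillna(False).astype(bool), "overseas")

    tally.output_count = len(df)
    return df.reset_index(drop=True), tally


def activity_filter(
    holdings: pd.DataFrame,
    events: pd.DataFrame,
    window: tuple | None = None,
) -> set[str]:
    """Holdings involved in at least one loading or unloading in the window.

    All other holdings are considered inactive and excluded downstream.
    """
    ev = events
    if window is not None:
        start, end = pd.to_datetime(window[0]), pd.to_datetime(window[1])
        ev = ev[ev["date"].between(start, end)]
    active = set(ev["holding_id"].dropna())
    return active & set(holdings["holding_id"])


def consistency_filter(
    movements: pd.DataFrame,
    holdings: pd.DataFrame,
    rules: frozenset | None = None,
) -> tuple[pd.DataFrame, int]:
    """Drop movements whose animal category is implausible for the origin farm.

    ``rules`` is a set of (animal_category, origin farm type) pairs to drop;
    defaults to :data:`swinenet.farmtypes.DEFAULT_INCONSISTENT_PAIRS`
    (barrows cannot leave farrowing-only farms, piglets cannot leave
    finishing-only farms, and so on).  The origin type column must be present
    in ``holdings`` as ``farm_type`` (see :mod:`swinenet.attributes`).
    """
    from .farmtypes import DEFAULT_INCONSISTENT_PAIRS

    rules = DEFAULT_INCONSISTENT_PAIRS if rules is None else rules
    types = holdings.set_index("holding_id")["farm_type"]
    origin_type = movements["origin_id"].map(types)
    bad = [
        (cat, typ) in rules
        for cat, typ in zip(movements["animal_category"], origin_type)
    ]
    bad = np.asarray(bad, dtype=bool)
    return movements[~bad].reset_index(drop=True), int(bad.sum())


def reconstruct_movements(events: pd.DataFrame) -> pd.DataFrame:
    """Turn loading/unloading event sequences into directed movements.

    Within each transport, events are ordered by ``sequence_index`` (ties by
    date).  A transport contributes nothing unless its ordered sequence
    starts with a loading.  Within each animal category, every loading is
    paired with every later unloading at a *different* holding, emitting one
    movement per (loading, subsequent unloading) pair; categories lacking
    either event kind contribute nothing.  The movement carries the loading
    date and the unloading head count (head counts are carried, not
    balanced).
    """
    if len(events) == 0:
        return pd.DataFrame(columns=MOVEMENT_COLUMNS)
    ordered = events.sort_values(["transport_id", "sequence_index", "date"],
                                 kind="mergesort")
    sizes = ordered.groupby("transport_id")["event_kind"].transform("size")

    # fast path: the overwhelmingly common two-event transport
    two = ordered[sizes == 2]
    pos = two.groupby("transport_id").cumcount()
    first = two[pos == 0].set_index("transport_id")
    second = two[pos == 1].set_index("transport_id")
    ok = (
        (first["event_kind"] == "loading")
        & (second["event_kind"] == "unloading")
        & (first["animal_category"] == second["animal_category"])
        & (first["holding_id"] != second["holding_id"])
    )
    fast = pd.DataFrame(
        {
            "origin_id": first.loc[ok, "holding_id"],
            "dest_id": second.loc[ok, "holding_id"],
            "date": first.loc[ok, "date"],
            "animal_category": first.loc[ok, "animal_category"],
            "head_count": second.loc[ok, "head_count"],
        }
    ).reset_index(drop=True)

    rows: list[tuple] = []
    for _, grp in ordered[sizes != 2].groupby("transport_id", sort=False):
        if grp.iloc[0]["event_kind"] != "loading":
            continue
        for _, cat_grp in grp.groupby("animal_category", sort=False):
            recs = cat_grp.to_dict("records")
            for a, load in enumerate(recs):
                if load["event_kind"] != "loading":
                    continue
                for unload in recs[a + 1:]:
                    if unload["event_kind"] != "unloading":
                        continue
                    if unload["holding_id"] == load["holding_id"]:
                        continue
                    rows.append(
                        (
                            load["holding_id"],
                            unload["holding_id"],
                            load["date"],
                            load["animal_category"],
                            unload["head_count"],
                        )
                    )
    slow = pd.DataFrame(rows, columns=MOVEMENT_COLUMNS)
    return pd.concat([fast, slow], ignore_index=True) if len(slow) else fast
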