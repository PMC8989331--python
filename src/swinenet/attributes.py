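"""Nodal attributes used as ERGM covariates.

Each active holding carries: an adapted farm type (the declared type promoted
to cover every husbandry area the holding actually reports, with nucleus and
multiplier status overriding the declaration), its industry sector, a size
class from within-type quartiles of a reference animal count, an estimated
batch-rearing system (BRS), company membership, outdoor housing and
insularity.

The BRS is a management scheme defined by how many batches of animals a farm
rears simultaneously (4, 5, 7, 10 or 20 batches); it is not declared in the
registry and is inferred here from the modal interval between consecutive
animal imports, as a proxy: a farm importing roughly every 5 weeks runs ~4
batches, one importing weekly runs ~20.  The inference is a heuristic and
its interval→BRS band table is configurable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .farmtypes import AREAS_TO_TYPE, TYPE_AREAS, sector_of

__all__ = [
    "adapt_farm_type",
    "classify_size",
    "estimate_brs",
    "derive_sector",
    "build_attribute_table",
    "DEFAULT_BRS_BANDS",
]

#: modal import-interval (days, inclusive bounds) → number of simultaneous
#: batches.  Follows standard French batch-management rhythms: a 4-batch
#: system imports about every 5 weeks, a 20-batch system about weekly.
DEFAULT_BRS_BANDS = (
    ((33, 42), "4"),
    ((24, 32), "5"),
    ((17, 23), "7"),
    ((10, 16), "10"),
    ((4, 9), "20"),
)


def adapt_farm_type(record) -> str:
    """Adapted farm type for one registry row (mapping-like or Series).

    Nucleus / multiplier production status overrides the activity-derived
    type.  Otherwise the declared husbandry activity is promoted to the
    smallest type consistent with every area the holding reports a non-zero
    capacity for (e.g. a declared finisher with a post-weaning area becomes a
    post-weaner/finisher; a holding reporting all three areas becomes
    farrow-to-finish).
    """
    production = record.get("production_type", "standard")
    if production == "nucleus":
        return "NU"
    if production == "multiplier":
        return "MU"
    declared = record["husbandry_activity"]
    if declared not in TYPE_AREAS or declared in ("BS", "NI", "MU", "NU"):
        return declared
    areas = set(TYPE_AREAS[declared])
    if record.get("cap_repro", 0) and record["cap_repro"] > 0:
        areas.add("repro")
    if record.get("cap_postwean", 0) and record["cap_postwean"] > 0:
        areas.add("postwean")
    if record.get("cap_fatten", 0) and record["cap_fatten"] > 0:
        areas.add("fatten")
    if not areas:
        return declared
    return AREAS_TO_TYPE[frozenset(areas)]


def reference_count(record) -> float:
    """Reference animal count nA for size classification.

    Holdings with a farrowing area are sized by their sow places; otherwise
    holdings with a post-weaning area by growing-pig places; the rest
    (finishing-only) by barrow places.
    """
    if record.get("cap_repro", 0) and record["cap_repro"] > 0:
        return float(record["cap_repro"])
    if record.get("cap_postwean", 0) and record["cap_postwean"] > 0:
        return float(record["cap_postwean"])
    return float(record.get("cap_fatten", 0) or 0)


def classify_size(farm_types: pd.Series, n_animals: pd.Series) -> pd.Series:
    """Within-type size class from quartiles of the reference count.

    For each farm type the 25th and 75th percentiles of nA (linear
    interpolation) define the classes: nA below the 25th percentile is
    ``small``, at or above the 75th is ``large``, in between ``regular``.
    Types with fewer than 4 holdings have degenerate quartiles and are all
    classed ``regular``.
    """
    out = pd.Series("regular", index=farm_types.index, dtype=object)
    for ftype, idx in farm_types.groupby(farm_types).groups.items():
        vals = n_animals.loc[idx].to_numpy(dtype=float)
        if len(vals) < 4:
            continue
        q25, q75 = np.percentile(vals, [25, 75])  # linear interpolation
        if q25 == q75:  # degenerate quartiles carry no size information
            continue
        cls = np.where(vals < q25, "small", np.where(vals >= q75, "large", "regular"))
        out.loc[idx] = cls
    return out


def small_thresholds(farm_types: pd.Series, n_animals: pd.Series) -> dict:
    """Per-type 25th percentile of nA (the small/regular boundary)."""
    thresholds = {}
    for ftype, idx in farm_types.groupby(farm_types).groups.items():
        vals = n_animals.loc[idx].to_numpy(dtype=float)
        if len(vals) >= 4:
            thresholds[ftype] = float(np.percentile(vals, 25))
    return thresholds


def estimate_brs(
    import_dates,
    capacity: float,
    small_threshold: float | None = None,
    bands=DEFAULT_BRS_BANDS,
) -> str:
    """Batch-rearing system from the modal inter-import interval.

    ``import_dates`` are the dates of incoming shipments (order irrelevant).
    The interval intD is the most frequent gap in days between consecutive
    imports, zero gaps (same-day shipments) discarded; ties go to the
    smallest gap.  intD is mapped through ``bands``; farms mapped to 10 or 20
    batches whose capacity falls below the type's small threshold are
    relabelled ``small.10`` / ``small.20``.  Fewer than two distinct import
    dates (no interval) → ``unidentifiable``.
    """
    dates = pd.to_datetime(pd.Series(list(import_dates))).sort_values()
    if len(dates) < 2:
        return "unidentifiable"
    gaps = dates.diff().dropna().dt.days.to_numpy()
    gaps = gaps[gaps > 0]
    if len(gaps) == 0:
        return "unidentifiable"
    values, counts = np.unique(gaps, return_counts=True)
    intd = int(values[np.argmax(counts)])  # ties: np.unique sorts ascending
    brs = "unidentifiable"
    for (lo, hi), label in bands:
        if lo <= intd <= hi:
            brs = label
            break
    if brs in ("10", "20") and small_threshold is not None and capacity < small_threshold:
        brs = f"small.{brs}"
    return brs


def derive_sector(farm_type: str) -> str:
    """breeding (MU/NU/BS) or growing; boar stations are dropped before ERGMs."""
    return sector_of(farm_type)


def build_attribute_table(
    holdings: pd.DataFrame,
    movements: pd.DataFrame | None = None,
    active: set | None = None,
) -> pd.DataFrame:
    """Derive the full nodal-attribute table, indexed by holding id.

    Columns: ``farm_type`` (adapted), ``sector``, ``size``, ``brs``,
    ``company``, ``outdoor``, ``insular``, plus coordinates for the distance
    covariate.  When ``movements`` are supplied the BRS is estimated from
    each holding's import dates; otherwise every holding is
    ``unidentifiable``.  ``active`` restricts the table to the active set.
    """
    df = holdings.copy()
    if active is not None:
        df = df[df["holding_id"].isin(active)]
    df = df.set_index("holding_id")
    farm_type = df.apply(adapt_farm_type, axis=1)
    n_animals = df.apply(reference_count, axis=1)
    size = classify_size(farm_type, n_animals)
    thresholds = small_thresholds(farm_type, n_animals)

    brs = pd.Series("unidentifiable", index=df.index, dtype=object)
    if movements is not None and len(movements):
        imports = movements.groupby("dest_id")["date"]
        for hid, dates in imports:
            if hid in df.index:
                brs.loc[hid] = estimate_brs(
                    dates, n_animals.loc[hid], thresholds.get(farm_type.loc[hid])
                )

    company = df["company_id"].fillna("independent").replace("", "independent")
    out = pd.DataFrame(
        {
            "farm_type": farm_type,
            "sector": farm_type.map(sector_of),
            "size": size,
            "brs": brs,
            "company": company,
            "outdoor": df["outdoor"].astype(bool),
            "insular": df["insular"].astype(bool),
            "x": df["x"],
            "y": df["y"],
        }
    )
    return out
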