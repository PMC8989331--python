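"""Synthetic holdings registries, trade networks and raw transport logs.

The real national movement database is confidential, so every downstream
stage is exercised on synthetic data that emulates its structure: a holdings
registry with the observed active-holding type mix, company membership,
outdoor and insularity flags and area capacities consistent with each farm
type; a ground-truth dyad-independent network model; and a raw transport
log of ordered loading/unloading events with configurable rates of the
defect classes the cleaning cascade removes (missing identifiers,
international and overseas legs, direct sales, animal removals, orphan
events, type-inconsistent shipments).

Every injected defect is tagged in a hidden ``_defect`` column and tallied
in a ledger, giving the cleaning audit an exact oracle.  All generation is
deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .ergm import ErgmModel, ErgmTerm, simulate_adjacency
from .farmtypes import (
    BREEDING_TYPES,
    DEFAULT_TYPE_PROPORTIONS,
    TYPE_AREAS,
)
from .ingest import EVENT_COLUMNS, HOLDING_COLUMNS
from .network import TradeNetwork

__all__ = [
    "SynthConfig",
    "generate_holdings",
    "default_ground_truth",
    "simulate_ergm_network",
    "route_category",
    "network_to_transport_log",
    "write_holdings",
    "write_transport_log",
]

#: defect classes the generator can inject, keyed by the cleaning-cascade
#: reason that removes them ("inconsistent" is removed later, by the
#: consistency filter on reconstructed movements).
DEFECT_CLASSES = (
    "international",
    "direct_sale_or_unmarked",
    "missing_id",
    "animal_removal",
    "unmatched_event",
    "overseas",
    "inconsistent",
)


@dataclass
class SynthConfig:
    """Parameters of the synthetic registry and transport-log generator.

    Defaults reproduce the study conditions: the active-holding type mix
    observed in the national database, a planar coordinate box roughly the
    size of metropolitan France (km), and moderate company concentration.
    """

    n_holdings: int = 1000
    type_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_TYPE_PROPORTIONS)
    )
    n_companies: int = 20
    company_assignment_prob: float = 0.7
    outdoor_prob: float = 0.1
    insular_prob: float = 0.01
    coordinate_box: tuple = (0.0, 1000.0, 0.0, 950.0)
    defect_rates: dict = field(default_factory=dict)
    seed: int = 0
    n_foreign: int = 2  # foreign-registered holdings available for defect legs
    n_overseas: int = 2  # overseas-territory holdings likewise

    def __post_init__(self) -> None:
        total = sum(self.type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type_proportions must sum to 1, got {total}")
        rates = {
            "company_assignment_prob": self.company_assignment_prob,
            "outdoor_prob": self.outdoor_prob,
            "insular_prob": self.insular_prob,
            **{f"defect_rates[{k}]": v for k, v in self.defect_rates.items()},
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        unknown = set(self.defect_rates) - set(DEFECT_CLASSES)
        if unknown:
            raise ValueError(f"unknown defect classes {sorted(unknown)}")
        if self.n_holdings <= 0:
            raise ValueError("n_holdings must be positive")

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "coordinate_box" in raw:
            raw["coordinate_box"] = tuple(raw["coordinate_box"])
        return cls(**raw)


# plausible capacity scales (head) per husbandry area
_CAP_SCALES = {"repro": (150, 0.6), "postwean": (900, 0.7), "fatten": (700, 0.7)}


def _capacity(rng: np.random.Generator, area: str) -> int:
    mean, sigma = _CAP_SCALES[area]
    return int(np.maximum(1, np.round(rng.lognormal(np.log(mean), sigma))))


def generate_holdings(config: SynthConfig) -> pd.DataFrame:
    """Generate a holdings registry DataFrame (schema of ``HOLDING_COLUMNS``).

    Farm types are drawn i.i.d. from ``type_proportions``; each holding gets
    planar coordinates in the configured box, a company (or independence),
    outdoor and insularity flags, and capacities consistent with its type's
    husbandry areas.  A handful of foreign and overseas holdings are appended
    so defect transports have somewhere to point; they never trade in the
    ground-truth network.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_holdings
    types = list(config.type_proportions)
    probs = np.array([config.type_proportions[t] for t in types], dtype=float)
    drawn = rng.choice(types, size=n, p=probs / probs.sum())

    xmin, xmax, ymin, ymax = config.coordinate_box
    xs = rng.uniform(xmin, xmax, size=n)
    ys = rng.uniform(ymin, ymax, size=n)
    in_company = rng.random(n) < config.company_assignment_prob
    company_ids = rng.integers(0, config.n_companies, size=n)

    rows = []
    for i in range(n):
        ftype = drawn[i]
        areas = TYPE_AREAS.get(ftype, frozenset())
        caps = {a: (_capacity(rng, a) if a in areas else 0)
                for a in ("repro", "postwean", "fatten")}
        if ftype == "NI":
            caps["fatten"] = int(rng.integers(1, 6))  # hobby-scale
        rows.append(
            {
                "holding_id": f"H{i:05d}",
                "owner_id": f"O{i:05d}",
                "x": round(float(xs[i]), 3),
                "y": round(float(ys[i]), 3),
                "country": "FR",
                "town": f"T{i % 997:03d}",
                "production_type": {"NU": "nucleus", "MU": "multiplier"}.get(
                    ftype, "standard"
                ),
                "husbandry_activity": ftype,
                "species": "pig",
                "outdoor": bool(rng.random() < config.outdoor_prob),
                "cap_repro": caps["repro"],
                "cap_postwean": caps["postwean"],
                "cap_fatten": caps["fatten"],
                "company_id": f"C{company_ids[i]:02d}" if in_company[i] else "independent",
                "overseas": False,
                "insular": bool(rng.random() < config.insular_prob),
                "record_date": "2016-01-01",
            }
        )
    for k in range(config.n_foreign):
        rows.append(_special_holding(f"XF{k:02d}", country="BE", overseas=False))
    for k in range(config.n_overseas):
        rows.append(_special_holding(f"XO{k:02d}", country="FR", overseas=True))
    df = pd.DataFrame(rows, columns=HOLDING_COLUMNS)
    df["record_date"] = pd.to_datetime(df["record_date"])
    return df


def _special_holding(hid: str, country: str, overseas: bool) -> dict:
    return {
        "holding_id": hid,
        "owner_id": f"O{hid}",
        "x": np.nan,
        "y": np.nan,
        "country": country,
        "town": "T-EXT",
        "production_type": "standard",
        "husbandry_activity": "FI",
        "species": "pig",
        "outdoor": False,
        "cap_repro": 0,
        "cap_postwean": 0,
        "cap_fatten": 100,
        "company_id": "independent",
        "overseas": overseas,
        "insular": False,
        "record_date": "2016-01-01",
    }


def default_ground_truth(density: float = 0.01) -> ErgmModel:
    """A plausible ground-truth model: sparse baseline, strong within-company
    homophily, extra nucleus→farrow-to-finish flow, farrowers as senders."""
    logit = float(np.log(density / (1.0 - density)))
    terms = [
        ErgmTerm("edges"),
        ErgmTerm("nodematch", "company"),
        ErgmTerm("nodemix", "farm_type", ("NU", "FF")),
        ErgmTerm("nodeofactor", "farm_type", "FA"),
    ]
    theta = np.array([logit, 2.0, 1.5, 1.0])
    return ErgmModel(terms=terms, theta=theta)


def simulate_ergm_network(
    attrs: pd.DataFrame,
    model: ErgmModel,
    seed: int,
    covariates: dict | None = None,
    window: tuple | None = None,
    subset_label: str = "whole",
) -> TradeNetwork:
    """Draw one network from a dyad-independent model over ``attrs``.

    Each ordered pair (i, j), i ≠ j, receives an edge independently with
    probability logistic(θ·δ_ij); no self-loops.
    """
    import networkx as nx

    A = simulate_adjacency(model, attrs, 1, seed, covariates)[0]
    nodes = list(attrs.index)
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    ii, jj = np.nonzero(A)
    g.add_edges_from((nodes[i], nodes[j]) for i, j in zip(ii, jj))
    return TradeNetwork(graph=g, attrs=attrs, window=window, subset_label=subset_label)


def route_category(origin_type: str, dest_type: str) -> str:
    """Animal category flowing on an edge, from the production-chain routing.

    Breeding herds export sows; farrowing farms export piglets; the rest of
    the growing chain trades growing pigs.  The routing never produces a
    (category, origin-type) pair the consistency filter would drop.
    """
    if origin_type in BREEDING_TYPES:
        return "sow"
    if origin_type in ("FA", "FPW"):
        return "piglet"
    if origin_type == "FF":
        return "piglet" if dest_type in ("PW", "PWF", "FI") else "growing_pig"
    return "growing_pig"


@dataclass
class Schedule:
    """Batching parameters for turning edges into dated transports."""

    window: tuple = ("2019-07-01", "2019-12-31")
    transports_per_edge: int = 3
    rhythms: tuple = (7, 14, 21, 28, 35)  # candidate import intervals (days)
    #: when set, each edge ships on the destination's rhythm across the whole
    #: window (stationary trade) instead of a burst of transports_per_edge
    cover_window: bool = False


def network_to_transport_log(
    network: TradeNetwork,
    schedule: Schedule | None = None,
    defect_rates: dict | None = None,
    seed: int = 0,
    foreign_ids: list | None = None,
    overseas_ids: list | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Expand a trade network into a raw event log, injecting tagged defects.

    Each edge becomes ``transports_per_edge`` transports spaced by the
    destination's import rhythm; every transport is a loading event at the
    origin followed (by sequence order) by an unloading event at the
    destination, with the animal category from :func:`route_category`.

    At most one defect class is drawn per transport, at the configured
    rates; affected records are tagged in the hidden ``_defect`` column.
    International and overseas defects re-point *both* events to dedicated
    foreign / overseas holdings so each removal reason's tally is exact.
    Returns the event log and a ledger mapping each defect class to the
    number of injected records (``inconsistent`` counts transports, since it
    is removed per reconstructed movement, not per record).
    """
    schedule = schedule or Schedule()
    defect_rates = defect_rates or {}
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(schedule.window[0])
    end = pd.Timestamp(schedule.window[1])
    span = (end - start).days

    ftype = network.attrs["farm_type"]
    if foreign_ids is None:
        foreign_ids = [h for h in network.attrs.index if str(h).startswith("XF")]
    if overseas_ids is None:
        overseas_ids = [h for h in network.attrs.index if str(h).startswith("XO")]

    classes = list(defect_rates)
    probs = np.array([defect_rates[c] for c in classes], dtype=float)
    if probs.sum() > 1.0:
        raise ValueError("defect rates must sum to at most 1")

    rhythm_of = {
        h: int(rng.choice(schedule.rhythms)) for h in network.attrs.index
    }
    ledger = {c: 0 for c in DEFECT_CLASSES}
    rows = []
    tid = 0
    for origin, dest in sorted(network.graph.edges()):
        category = network.graph.edges[origin, dest].get(
            "animal_category", route_category(ftype.get(origin, "FI"), ftype.get(dest, "FI"))
        )
        rhythm = rhythm_of[dest]
        if schedule.cover_window:
            phase = int(rng.integers(0, rhythm))
            offsets = range(phase, span + 1, rhythm)
        else:
            n_tr = schedule.transports_per_edge
            phase = int(rng.integers(0, max(1, span - rhythm * (n_tr - 1))))
            offsets = [min(phase + j * rhythm, span) for j in range(n_tr)]
        for off in offsets:
            date = start + pd.Timedelta(days=off)
            defect = None
            if classes:
                u = rng.random()
                acc = 0.0
                for c, p in zip(classes, probs):
                    acc += p
                    if u < acc:
                        defect = c
                        break
            transport_id = f"T{tid:06d}"
            tid += 1
            head = int(rng.integers(5, 200))
            load = {
                "transport_id": transport_id, "event_kind": "loading",
                "holding_id": origin, "date": date, "animal_category": category,
                "head_count": head, "sequence_index": 0,
                "movement_kind": "commercial", "_defect": "",
            }
            unload = {**load, "event_kind": "unloading", "holding_id": dest,
                      "sequence_index": 1}
            defect = _apply_defect(
                defect, load, unload, ftype, foreign_ids, overseas_ids, rng
            )
            if defect == "unmatched_event":
                ledger[defect] += 1
                rows.append(unload)
                continue
            if defect is not None:
                ledger[defect] += 2 if defect != "inconsistent" else 1
            rows.append(load)
            rows.append(unload)
    log = pd.DataFrame(rows, columns=EVENT_COLUMNS + ["_defect"])
    return log, ledger


def _apply_defect(defect, load, unload, ftype, foreign_ids, overseas_ids, rng):
    """Mutate one transport's events in place; return the class actually applied."""
    if defect is None:
        return None
    if defect == "missing_id":
        load["transport_id"] = unload["transport_id"] = ""
    elif defect == "international":
        if not foreign_ids:
            return None
        load["holding_id"] = foreign_ids[int(rng.integers(len(foreign_ids)))]
        unload["holding_id"] = foreign_ids[int(rng.integers(len(foreign_ids)))]
    elif defect == "overseas":
        if not overseas_ids:
            return None
        load["holding_id"] = overseas_ids[int(rng.integers(len(overseas_ids)))]
        unload["holding_id"] = overseas_ids[int(rng.integers(len(overseas_ids)))]
    elif defect == "direct_sale_or_unmarked":
        kind = ("direct_sale", "household_slaughter", "unmarked")[int(rng.integers(3))]
        load["movement_kind"] = unload["movement_kind"] = kind
    elif defect == "animal_removal":
        load["movement_kind"] = unload["movement_kind"] = "removal"
    elif defect == "unmatched_event":
        pass  # caller drops the loading record
    elif defect == "inconsistent":
        from .farmtypes import DEFAULT_INCONSISTENT_PAIRS

        origin_type = ftype.get(load["holding_id"], None)
        bad = [cat for cat, typ in DEFAULT_INCONSISTENT_PAIRS if typ == origin_type]
        if not bad:
            return None  # no implausible category exists for this origin type
        cat = sorted(bad)[int(rng.integers(len(bad)))]
        load["animal_category"] = unload["animal_category"] = cat
    else:
        raise ValueError(f"unknown defect class {defect!r}")
    if defect != "inconsistent":
        load["_defect"] = unload["_defect"] = defect
    else:
        load["_defect"] = unload["_defect"] = "inconsistent"
    return defect


def write_holdings(holdings: pd.DataFrame, path) -> None:
    """Write the registry CSV in the schema ``read_holdings`` expects."""
    holdings.to_csv(path, index=False, date_format="%Y-%m-%d")


def write_transport_log(events: pd.DataFrame, path) -> None:
    """Write the event-log CSV (the synthetic ``_defect`` tag included)."""
    events.to_csv(path, index=False, date_format="%Y-%m-%d")
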