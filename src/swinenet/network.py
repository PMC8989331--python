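"""Directed, unweighted trade networks built from movement subsets.

A :class:`TradeNetwork` is a directed graph over active holdings: nodes are
holdings involved in at least one kept movement, edges are ordered
origin→destination pairs with parallel and repeated shipments collapsed to a
single tie (the analysis is unweighted), plus the nodal-attribute table and
coordinates for the geographic distance covariate.

Networks can be restricted to a time window, to a production sector
(breeding = nucleus/multiplier/boar-station herds; growing = the
farrow-to-finish chain), or to a single transported animal category (sows,
piglets, growing pigs).  Barrow and cull shipments are excluded from the
analysis networks because their consistency is uncertain, and boar stations
— epidemiological dead ends under strict biosecurity — can be dropped for
model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .farmtypes import BREEDING_TYPES, GROWING_TYPES

__all__ = ["TradeNetwork", "build_network", "SUBSET_LABELS"]

SUBSET_LABELS = ("whole", "breeding", "growing", "sows", "piglets", "growing_pigs")

_CATEGORY_SUBSETS = {
    "sows": "sow",
    "piglets": "piglet",
    "growing_pigs": "growing_pig",
}

#: shipments of barrows (castrated males headed for slaughter) and culled
#: animals are dropped from analysis networks.
EXCLUDED_CATEGORIES = frozenset({"barrow", "cull"})


@dataclass
class TradeNetwork:
    """A directed unweighted trade network with nodal attributes."""

    graph: nx.DiGraph
    attrs: pd.DataFrame  # indexed by holding id, aligned with graph nodes
    window: tuple | None = None
    subset_label: str = "whole"

    @property
    def nodes(self) -> list:
        return list(self.attrs.index)

    @property
    def n_nodes(self) -> int:
        return len(self.attrs)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def adjacency(self) -> np.ndarray:
        """0/1 adjacency matrix in the row order of ``attrs``."""
        return nx.to_numpy_array(self.graph, nodelist=self.nodes, dtype=int)

    def distance_matrix(self) -> np.ndarray:
        """Symmetric Euclidean inter-holding distances (km), zero diagonal."""
        xy = self.attrs[["x", "y"]].to_numpy(dtype=float)
        diff = xy[:, None, :] - xy[None, :, :]
        return np.hypot(diff[..., 0], diff[..., 1])

    def edge_list(self) -> pd.DataFrame:
        return pd.DataFrame(self.graph.edges(), columns=["origin_id", "dest_id"])


def build_network(
    movements: pd.DataFrame,
    attrs: pd.DataFrame,
    window: tuple | None = None,
    subset: str = "whole",
    drop_bs: bool = False,
    excluded_categories: frozenset = EXCLUDED_CATEGORIES,
) -> TradeNetwork:
    """Build the directed unweighted network for one movement subset.

    ``attrs`` is the nodal-attribute table from
    :func:`swinenet.attributes.build_attribute_table`.  Sector subsets
    restrict *both* endpoints to the sector's farm types; category subsets
    keep a single animal category.  Nodes are the holdings incident to at
    least one kept movement; repeated movements collapse to one edge and
    self-loops never arise (movement reconstruction forbids them).
    """
    if subset not in SUBSET_LABELS:
        raise ValueError(f"unknown subset {subset!r}; expected one of {SUBSET_LABELS}")
    mov = movements
    if window is not None:
        start, end = pd.to_datetime(window[0]), pd.to_datetime(window[1])
        mov = mov[mov["date"].between(start, end)]
    mov = mov[~mov["animal_category"].isin(excluded_categories)]
    if subset in _CATEGORY_SUBSETS:
        mov = mov[mov["animal_category"] == _CATEGORY_SUBSETS[subset]]

    ftype = attrs["farm_type"]
    allowed = set(attrs.index)
    if subset == "breeding":
        allowed = set(ftype[ftype.isin(BREEDING_TYPES)].index)
    elif subset == "growing":
        allowed = set(ftype[ftype.isin(GROWING_TYPES)].index)
    if drop_bs:
        allowed -= set(ftype[ftype == "BS"].index)
    mov = mov[mov["origin_id"].isin(allowed) & mov["dest_id"].isin(allowed)]

    edges = set(zip(mov["origin_id"], mov["dest_id"]))
    nodes = sorted({o for o, _ in edges} | {d for _, d in edges})
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    node_attrs = attrs.loc[nodes]
    for col in node_attrs.columns:
        nx.set_node_attributes(g, node_attrs[col].to_dict(), name=col)
    return TradeNetwork(graph=g, attrs=node_attrs, window=window, subset_label=subset)
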