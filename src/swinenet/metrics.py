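"""Descriptive network indicators for trade networks.

The indicator suite characterises the structure of a directed, unweighted
trade network: order and size, median non-zero in/out-degrees, average
relative betweenness, weakly and strongly connected components, transitivity
of the undirected collapse, density, diameter and average path length over
reachable pairs, degree assortativity, reciprocity, the proportion of
holdings with an average Jaccard neighbourhood-similarity of zero, and the
average geographic length of a trade link.

Degenerate inputs (empty networks, no senders) yield missing values (NaN),
never zero.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .network import TradeNetwork, build_network

__all__ = ["compute_metrics", "metrics_timeseries", "METRIC_NAMES", "geodesic_lengths"]

METRIC_NAMES = [
    "n_nodes", "n_edges",
    "median_indegree", "median_outdegree",
    "average_relative_betweenness",
    "n_wcc", "n_scc",
    "transitivity", "density", "diameter",
    "degree_assortativity", "reciprocity",
    "average_path_length", "jaccard_zero_proportion",
    "average_distance",
]


def geodesic_lengths(net: TradeNetwork) -> np.ndarray:
    """n×n matrix of directed shortest-path lengths (inf where unreachable)."""
    A = csr_matrix(net.adjacency())
    return shortest_path(A, method="D", unweighted=True)


def _median_nonzero(values: np.ndarray) -> float:
    nz = values[values > 0]
    return float(np.median(nz)) if len(nz) else np.nan


def _degree_assortativity(net: TradeNetwork) -> float:
    """Pearson correlation of total degree at the two endpoints of each edge."""
    g = net.graph
    if g.number_of_edges() < 2:
        return np.nan
    deg = dict(g.degree())  # total degree = in + out
    du = np.array([deg[u] for u, _ in g.edges()], dtype=float)
    dv = np.array([deg[v] for _, v in g.edges()], dtype=float)
    if du.std() == 0 or dv.std() == 0:
        return np.nan
    return float(np.corrcoef(du, dv)[0, 1])


def _jaccard_zero_proportion(net: TradeNetwork) -> float:
    """Fraction of holdings whose mean Jaccard similarity to all others is 0.

    Neighbourhoods are undirected (a neighbour is any adjacent holding); the
    Jaccard coefficient of two empty or disjoint neighbourhoods is 0, so a
    node scores zero iff it shares no neighbour with any other node.
    """
    n = net.n_nodes
    if n < 2:
        return np.nan
    A = net.adjacency()
    U = ((A + A.T) > 0).astype(int)
    inter = U @ U  # |N(i) ∩ N(j)| off-diagonal
    np.fill_diagonal(inter, 0)
    zero = (inter.sum(axis=1) == 0)
    return float(np.mean(zero))


def _average_distance(net: TradeNetwork, universe: str = "edges") -> float:
    """Mean Euclidean distance (km), over trade links by default."""
    if net.attrs[["x", "y"]].isna().any().any():
        return np.nan
    D = net.distance_matrix()
    if universe == "edges":
        A = net.adjacency().astype(bool)
        return float(D[A].mean()) if A.any() else np.nan
    mask = ~np.eye(net.n_nodes, dtype=bool)
    return float(D[mask].mean()) if mask.any() else np.nan


def compute_metrics(net: TradeNetwork, distance_universe: str = "edges") -> dict:
    """One row of indicator values for a network.

    Path-based indicators (diameter, average path length) are taken over
    reachable ordered pairs only; transitivity is global clustering on the
    undirected collapse (every triadic configuration counted as transitive,
    direction ignored); betweenness is normalised by its theoretical maximum
    (n−1)(n−2) for directed graphs.
    """
    n, m = net.n_nodes, net.n_edges
    row = {name: np.nan for name in METRIC_NAMES}
    row["n_nodes"], row["n_edges"] = n, m
    if n == 0:
        row["jaccard_zero_proportion"] = np.nan
        return row

    g = net.graph
    indeg = np.array([d for _, d in g.in_degree()], dtype=float)
    outdeg = np.array([d for _, d in g.out_degree()], dtype=float)
    row["median_indegree"] = _median_nonzero(indeg)
    row["median_outdegree"] = _median_nonzero(outdeg)

    if n > 2:
        bw = nx.betweenness_centrality(g, normalized=True)
        row["average_relative_betweenness"] = float(np.mean(list(bw.values())))
    row["n_wcc"] = nx.number_weakly_connected_components(g)
    row["n_scc"] = nx.number_strongly_connected_components(g)
    if n >= 3:
        und = g.to_undirected()
        n_triples = sum(d * (d - 1) for _, d in und.degree())
        row["transitivity"] = float(nx.transitivity(und)) if n_triples else np.nan
    row["density"] = m / (n * (n - 1)) if n > 1 else np.nan

    if m:
        L = geodesic_lengths(net)
        off = ~np.eye(n, dtype=bool)
        finite = np.isfinite(L) & off
        if finite.any():
            row["diameter"] = float(L[finite].max())
            row["average_path_length"] = float(L[finite].mean())
        recip = sum(1 for u, v in g.edges() if g.has_edge(v, u))
        row["reciprocity"] = recip / m
    row["degree_assortativity"] = _degree_assortativity(net)
    row["jaccard_zero_proportion"] = _jaccard_zero_proportion(net)
    row["average_distance"] = _average_distance(net, distance_universe)
    return row


def _windows(dates: pd.Series, granularity: str) -> list[tuple]:
    start, end = dates.min(), dates.max()
    if granularity == "monthly":
        periods = pd.period_range(start, end, freq="M")
        return [(p.start_time, p.end_time.normalize()) for p in periods]
    if granularity == "semestrial":
        out = []
        for year in range(start.year, end.year + 1):
            for lo, hi in ((f"{year}-01-01", f"{year}-06-30"),
                           (f"{year}-07-01", f"{year}-12-31")):
                lo_t, hi_t = pd.Timestamp(lo), pd.Timestamp(hi)
                if hi_t >= start and lo_t <= end:
                    out.append((lo_t, hi_t))
        return out
    if granularity == "annual":
        return [
            (pd.Timestamp(f"{y}-01-01"), pd.Timestamp(f"{y}-12-31"))
            for y in range(start.year, end.year + 1)
        ]
    raise ValueError(f"unknown granularity {granularity!r}")


def metrics_timeseries(
    movements: pd.DataFrame,
    attrs: pd.DataFrame,
    granularity: str = "semestrial",
    subset: str = "whole",
) -> pd.DataFrame:
    """Indicator rows per calendar window (months, Jan–Jun / Jul–Dec
    semesters, or years) for one movement subset.

    Windows inside the movement span with no movements yield rows of missing
    values rather than being skipped.
    """
    if len(movements) == 0:
        return pd.DataFrame(columns=["window_start", "window_end", "subset", *METRIC_NAMES])
    dates = pd.to_datetime(movements["date"])
    rows = []
    for lo, hi in _windows(dates, granularity):
        net = build_network(movements, attrs, window=(lo, hi), subset=subset)
        row = compute_metrics(net)
        rows.append({"window_start": lo, "window_end": hi, "subset": subset, **row})
    return pd.DataFrame(rows)
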