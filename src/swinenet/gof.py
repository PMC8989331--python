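"""Goodness of fit for fitted network models by simulation.

A fitted dyad-independent model is judged by simulating an ensemble of
networks over the observed node set and comparing six structural statistics
of the observed network to the simulated distributions, bin by bin:
in-degree and out-degree distributions, the minimum geodesic distance
distribution, the 16-class directed triad census, and the edge-wise and
dyad-wise shared-partner distributions.  The simulated ensemble is
summarised by percentile envelopes (2.5/25/50/75/97.5); an observed bin is
covered when it lies inside the central 95% envelope.  Out-of-sample
performance is assessed by repeating the comparison against networks
observed in other time windows (cross-validation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .ergm import ErgmModel, build_design, network_statistics, simulate_adjacency
from .network import TradeNetwork

__all__ = [
    "TRIAD_CLASSES",
    "GofReport",
    "triad_census",
    "shared_partner_distributions",
    "geodesic_distribution",
    "degree_distribution",
    "gof_compare",
    "cross_validate",
]

#: the 16 isomorphism classes of directed three-node subgraphs, in the
#: conventional MAN (mutual/asymmetric/null) labelling.
TRIAD_CLASSES = (
    "003", "012", "102", "021D", "021U", "021C", "111D", "111U",
    "030T", "030C", "201", "120D", "120U", "120C", "210", "300",
)

ENVELOPE_PERCENTILES = (2.5, 25.0, 50.0, 75.0, 97.5)


def _as_digraph(adjacency: np.ndarray) -> nx.DiGraph:
    g = nx.DiGraph()
    n = adjacency.shape[0]
    g.add_nodes_from(range(n))
    ii, jj = np.nonzero(adjacency)
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    return g


_TRIAD_LUT: np.ndarray | None = None
_TRIPLE_CACHE: dict[int, tuple] = {}


def _triad_lookup_table() -> np.ndarray:
    """Map the 6-bit dyad code of a node triple to its triad-class index.

    The code packs the six possible arcs among an ordered triple (i, j, k):
    bit 0 = i→j, 1 = j→i, 2 = i→k, 3 = k→i, 4 = j→k, 5 = k→j.  Each of the
    64 codes is classified once via the canonical single-triad census.
    """
    global _TRIAD_LUT
    if _TRIAD_LUT is None:
        lut = np.empty(64, dtype=np.int8)
        arcs = [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)]
        for code in range(64):
            g = nx.DiGraph()
            g.add_nodes_from(range(3))
            g.add_edges_from(a for b, a in enumerate(arcs) if code >> b & 1)
            census = nx.triadic_census(g)
            (label,) = [k for k, v in census.items() if v]
            lut[code] = TRIAD_CLASSES.index(label)
        _TRIAD_LUT = lut
    return _TRIAD_LUT


def _triples(n: int) -> tuple:
    """Index arrays (i, j, k) of all unordered triples with i < j < k."""
    if n not in _TRIPLE_CACHE:
        ii, jj, kk = [], [], []
        for i in range(n - 2):
            j, k = np.triu_indices(n - i - 1, k=1)
            jj.append(j + i + 1)
            kk.append(k + i + 1)
            ii.append(np.full(len(j), i))
        if ii:
            _TRIPLE_CACHE[n] = tuple(np.concatenate(a) for a in (ii, jj, kk))
        else:
            _TRIPLE_CACHE[n] = (np.array([], int),) * 3
    return _TRIPLE_CACHE[n]


def triad_census(adjacency: np.ndarray) -> dict[str, int]:
    """Counts of the 16 directed-triad classes over all unordered triples.

    Vectorised: every triple's six arc indicators are packed into a 6-bit
    code and classified through a precomputed lookup table; counts over all
    C(n, 3) triples come from one bincount.
    """
    A = np.asarray(adjacency, dtype=np.int8)
    n = A.shape[0]
    if n < 3:
        return {k: 0 for k in TRIAD_CLASSES}
    i, j, k = _triples(n)
    code = (
        A[i, j]
        | (A[j, i] << 1)
        | (A[i, k] << 2)
        | (A[k, i] << 3)
        | (A[j, k] << 4)
        | (A[k, j] << 5)
    )
    classes = _triad_lookup_table()[code]
    counts = np.bincount(classes, minlength=16)
    return {name: int(c) for name, c in zip(TRIAD_CLASSES, counts)}


def degree_distribution(adjacency: np.ndarray, direction: str) -> dict[int, int]:
    """Histogram of in- or out-degrees (``direction`` = 'in' | 'out')."""
    axis = 0 if direction == "in" else 1
    deg = np.asarray(adjacency).sum(axis=axis)
    values, counts = np.unique(deg, return_counts=True)
    return {int(v): int(c) for v, c in zip(values, counts)}


def geodesic_distribution(adjacency: np.ndarray) -> dict:
    """Counts of ordered node pairs per finite geodesic distance.

    Unreachable pairs are tallied under the key ``"inf"``; the counts sum to
    n(n−1).
    """
    n = adjacency.shape[0]
    if n < 2:
        return {"inf": 0}
    L = shortest_path(csr_matrix(adjacency), method="D", unweighted=True)
    off = ~np.eye(n, dtype=bool)
    vals = L[off]
    finite = vals[np.isfinite(vals)].astype(int)
    hist: dict = {}
    values, counts = np.unique(finite, return_counts=True)
    for v, c in zip(values, counts):
        hist[int(v)] = int(c)
    hist["inf"] = int(np.sum(~np.isfinite(vals)))
    return hist


def shared_partner_distributions(adjacency: np.ndarray, mode: str) -> dict[int, int]:
    """Edge-wise or dyad-wise shared-partner histogram.

    A shared partner of (i, j) is a third node adjacent — ignoring direction
    — to both i and j.  ``edgewise`` counts one entry per directed edge
    (total = number of edges); ``dyadwise`` one per unordered node pair
    (total = C(n, 2)).
    """
    A = np.asarray(adjacency)
    n = A.shape[0]
    U = ((A + A.T) > 0).astype(int)
    common = U @ U
    if mode == "edgewise":
        ii, jj = np.nonzero(A)
        counts = common[ii, jj]
    elif mode == "dyadwise":
        iu = np.triu_indices(n, k=1)
        counts = common[iu]
    else:
        raise ValueError(f"mode must be 'edgewise' or 'dyadwise', got {mode!r}")
    values, freqs = np.unique(counts, return_counts=True)
    return {int(v): int(c) for v, c in zip(values, freqs)}


def six_statistics(adjacency: np.ndarray) -> dict[str, dict]:
    """All six structural statistics for one network."""
    return {
        "indegree": degree_distribution(adjacency, "in"),
        "outdegree": degree_distribution(adjacency, "out"),
        "geodesic": geodesic_distribution(adjacency),
        "triad_census": triad_census(adjacency),
        "esp": shared_partner_distributions(adjacency, "edgewise"),
        "dsp": shared_partner_distributions(adjacency, "dyadwise"),
    }


@dataclass
class GofReport:
    """Envelope comparison of observed vs simulated structural statistics."""

    statistics: dict = field(default_factory=dict)
    in_model: pd.DataFrame | None = None
    n_sims: int = 0
    seed: int | None = None
    window_label: str | None = None

    def coverage(self, statistic: str) -> float:
        """Fraction of observed bins inside the central 95% envelope."""
        entry = self.statistics[statistic]
        flags = entry["covered"]
        return float(np.mean(flags)) if len(flags) else np.nan

    def to_dict(self) -> dict:
        out = {
            "n_sims": self.n_sims,
            "seed": self.seed,
            "window_label": self.window_label,
            "statistics": {},
        }
        for name, entry in self.statistics.items():
            out["statistics"][name] = {
                "bins": [str(b) for b in entry["bins"]],
                "observed": entry["observed"].tolist(),
                "envelopes": {str(p): entry["envelopes"][p].tolist()
                              for p in ENVELOPE_PERCENTILES},
                "covered": entry["covered"].tolist(),
                "coverage": self.coverage(name),
            }
        if self.in_model is not None:
            out["in_model"] = self.in_model.to_dict(orient="records")
        return out


def _align(observed: dict, simulated: list[dict]) -> tuple[list, np.ndarray, np.ndarray]:
    """Union of bins; observed vector and (n_sims, n_bins) simulated matrix."""
    keys: set = set(observed)
    for s in simulated:
        keys |= set(s)

    def sort_key(k):
        return (1, 0) if k == "inf" else (0, k) if isinstance(k, (int, np.integer)) else (0, 0)

    if all(isinstance(k, str) for k in keys):  # triad census: fixed order
        bins = [k for k in TRIAD_CLASSES if k in keys]
    else:
        bins = sorted(keys, key=sort_key)
    obs = np.array([observed.get(b, 0) for b in bins], dtype=float)
    sims = np.array([[s.get(b, 0) for b in bins] for s in simulated], dtype=float)
    return bins, obs, sims


def gof_compare(
    observed: TradeNetwork,
    model: ErgmModel,
    n_sims: int = 500,
    seed: int = 0,
    covariates: dict | None = None,
) -> GofReport:
    """Compare an observed network to an ensemble simulated from ``model``.

    Simulates ``n_sims`` networks over the observed node set, computes the
    six structural statistics for each, and flags every observed bin lying
    outside the simulated 95% envelope.  Also reports the in-model
    statistics: for each model term, the observed statistic against the
    simulated distribution (for an exactly-fitted dyad-independent model the
    simulated mean equals the observed value in expectation).
    """
    A_obs = observed.adjacency()
    obs_stats = six_statistics(A_obs)
    sims = simulate_adjacency(model, observed.attrs, n_sims, seed, covariates)
    sim_stats = [six_statistics(A) for A in sims]

    report = GofReport(n_sims=n_sims, seed=seed,
                       window_label=str(observed.window))
    for name in obs_stats:
        bins, obs, mat = _align(obs_stats[name], [s[name] for s in sim_stats])
        envelopes = {p: np.percentile(mat, p, axis=0) for p in ENVELOPE_PERCENTILES}
        covered = (obs >= envelopes[2.5]) & (obs <= envelopes[97.5])
        report.statistics[name] = {
            "bins": bins,
            "observed": obs,
            "envelopes": envelopes,
            "covered": covered,
        }

    design = build_design(A_obs, observed.attrs, model.terms, covariates)
    g_obs = network_statistics(design)
    mask = ~np.eye(A_obs.shape[0], dtype=bool)
    sim_g = np.array([design.X.T @ A[mask].astype(float) for A in sims])
    report.in_model = pd.DataFrame(
        {
            "term": model.labels,
            "observed": g_obs,
            "simulated_mean": sim_g.mean(axis=0),
            "simulated_p2.5": np.percentile(sim_g, 2.5, axis=0),
            "simulated_p97.5": np.percentile(sim_g, 97.5, axis=0),
        }
    )
    return report


def cross_validate(
    model: ErgmModel,
    other_windows: list[TradeNetwork],
    n_sims: int = 500,
    seed: int = 0,
    covariates_per_window: list[dict] | None = None,
) -> list[GofReport]:
    """Out-of-sample goodness of fit against networks from other windows.

    For each held-out window the model is simulated over *that* window's
    active node set (attributes may differ between windows) and compared to
    the network observed there.  Empty windows yield an empty report.
    """
    reports = []
    for k, net in enumerate(other_windows):
        cov = covariates_per_window[k] if covariates_per_window else None
        if net.n_nodes == 0:
            reports.append(
                GofReport(n_sims=0, seed=seed, window_label=str(net.window))
            )
            continue
        reports.append(gof_compare(net, model, n_sims=n_sims, seed=seed + k, covariates=cov))
    return reports
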