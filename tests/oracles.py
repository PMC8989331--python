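"""Brute-force reference implementations for tiny graphs.

Everything here is written with explicit loops and first-principles
definitions (Floyd–Warshall distances, exhaustive triple enumeration,
path-count dynamic programming) so it is independent of the package's
vectorised / library-backed implementations.  Intended for n ≤ 8.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np

INF = math.inf


def floyd_warshall(A: np.ndarray) -> np.ndarray:
    n = A.shape[0]
    D = np.full((n, n), INF)
    for i in range(n):
        D[i, i] = 0.0
        for j in range(n):
            if i != j and A[i, j]:
                D[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def shortest_path_counts(A: np.ndarray, D: np.ndarray) -> np.ndarray:
    """sigma[s, t] = number of distinct shortest s→t paths."""
    n = A.shape[0]
    sigma = np.zeros((n, n))
    for s in range(n):
        order = sorted(range(n), key=lambda v: D[s, v])
        sigma[s, s] = 1.0
        for v in order:
            if v == s or D[s, v] == INF:
                continue
            sigma[s, v] = sum(
                sigma[s, u] for u in range(n) if A[u, v] and D[s, u] + 1 == D[s, v]
            )
    return sigma


def betweenness(A: np.ndarray) -> np.ndarray:
    """Directed betweenness per node, relative to the (n−1)(n−2) maximum."""
    n = A.shape[0]
    D = floyd_warshall(A)
    sigma = shortest_path_counts(A, D)
    bw = np.zeros(n)
    for v in range(n):
        for s in range(n):
            for t in range(n):
                if len({s, t, v}) < 3 or D[s, t] == INF or sigma[s, t] == 0:
                    continue
                if D[s, v] + D[v, t] == D[s, t]:
                    bw[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    if n > 2:
        bw /= (n - 1) * (n - 2)
    return bw


def reachability_components(A: np.ndarray) -> tuple[int, int]:
    """(number of weakly cc, number of strongly cc) by explicit reachability."""
    n = A.shape[0]
    D = floyd_warshall(A)
    U = ((A + A.T) > 0).astype(int)
    DU = floyd_warshall(U)
    seen: list[set] = []
    for i in range(n):
        for comp in seen:
            if DU[i, next(iter(comp))] < INF:
                comp.add(i)
                break
        else:
            seen.append({i})
    strong: list[set] = []
    for i in range(n):
        for comp in strong:
            j = next(iter(comp))
            if D[i, j] < INF and D[j, i] < INF:
                comp.add(i)
                break
        else:
            strong.append({i})
    return len(seen), len(strong)


def transitivity_undirected(A: np.ndarray) -> float:
    """Global clustering of the undirected collapse: 3·triangles / open+closed triples."""
    n = A.shape[0]
    U = ((A + A.T) > 0).astype(int)
    closed = 0
    triples = 0
    for i, j, k in itertools.permutations(range(n), 3):
        if U[j, i] and U[i, k]:  # path j-i-k centred on i
            triples += 1
            if U[j, k]:
                closed += 1
    return closed / triples if triples else float("nan")


def metrics_reference(A: np.ndarray, coords: np.ndarray | None = None) -> dict:
    """The full indicator suite computed from first principles."""
    n = A.shape[0]
    m = int(A.sum())
    D = floyd_warshall(A)
    indeg = A.sum(axis=0)
    outdeg = A.sum(axis=1)
    deg = indeg + outdeg

    def med_nonzero(v):
        nz = sorted(x for x in v if x > 0)
        if not nz:
            return float("nan")
        mid = len(nz) // 2
        return float(nz[mid]) if len(nz) % 2 else (nz[mid - 1] + nz[mid]) / 2.0

    finite = [D[i, j] for i in range(n) for j in range(n) if i != j and D[i, j] < INF]
    edges = [(i, j) for i in range(n) for j in range(n) if A[i, j]]
    if len(edges) >= 2:
        du = [deg[i] for i, _ in edges]
        dv = [deg[j] for _, j in edges]
        mu, mv = np.mean(du), np.mean(dv)
        num = sum((a - mu) * (b - mv) for a, b in zip(du, dv))
        den = math.sqrt(sum((a - mu) ** 2 for a in du) * sum((b - mv) ** 2 for b in dv))
        assort = num / den if den else float("nan")
    else:
        assort = float("nan")

    U = ((A + A.T) > 0).astype(int)
    jacc_zero = float("nan")
    if n >= 2:
        zero = 0
        for i in range(n):
            sims = []
            for j in range(n):
                if j == i:
                    continue
                ni = {k for k in range(n) if U[i, k]}
                nj = {k for k in range(n) if U[j, k]}
                union = ni | nj
                sims.append(len(ni & nj) / len(union) if union else 0.0)
            if all(s == 0 for s in sims):
                zero += 1
        jacc_zero = zero / n

    wcc, scc = reachability_components(A)
    out = {
        "n_nodes": n,
        "n_edges": m,
        "median_indegree": med_nonzero(indeg),
        "median_outdegree": med_nonzero(outdeg),
        "average_relative_betweenness": float(np.mean(betweenness(A))) if n > 2 else float("nan"),
        "n_wcc": wcc,
        "n_scc": scc,
        "transitivity": transitivity_undirected(A) if n >= 3 else float("nan"),
        "density": m / (n * (n - 1)) if n > 1 else float("nan"),
        "diameter": max(finite) if finite and m else float("nan"),
        "degree_assortativity": assort,
        "reciprocity": (
            sum(1 for i, j in edges if A[j, i]) / m if m else float("nan")
        ),
        "average_path_length": (sum(finite) / len(finite)) if finite and m else float("nan"),
        "jaccard_zero_proportion": jacc_zero,
    }
    if coords is not None:
        dist = [
            math.hypot(*(coords[i] - coords[j])) for i, j in edges
        ]
        out["average_distance"] = sum(dist) / len(dist) if dist else float("nan")
    return out


def triad_census_reference(A: np.ndarray) -> dict[str, int]:
    """Census by classifying each induced 3-node subgraph separately."""
    n = A.shape[0]
    counts: dict[str, int] = {}
    for tri in itertools.combinations(range(n), 3):
        g = nx.DiGraph()
        g.add_nodes_from(range(3))
        for a, b in itertools.permutations(range(3), 2):
            if A[tri[a], tri[b]]:
                g.add_edge(a, b)
        census = nx.triadic_census(g)
        (label,) = [k for k, v in census.items() if v]
        counts[label] = counts.get(label, 0) + 1
    return counts


def geodesic_reference(A: np.ndarray) -> dict:
    n = A.shape[0]
    D = floyd_warshall(A)
    hist: dict = {}
    unreachable = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if D[i, j] == INF:
                unreachable += 1
            else:
                d = int(D[i, j])
                hist[d] = hist.get(d, 0) + 1
    hist["inf"] = unreachable
    return hist


def shared_partners_reference(A: np.ndarray, mode: str) -> dict[int, int]:
    n = A.shape[0]
    U = ((A + A.T) > 0).astype(int)

    def common(i, j):
        return sum(1 for k in range(n) if k not in (i, j) and U[i, k] and U[j, k])

    hist: dict[int, int] = {}
    if mode == "edgewise":
        pairs = [(i, j) for i in range(n) for j in range(n) if A[i, j]]
    else:
        pairs = list(itertools.combinations(range(n), 2))
    for i, j in pairs:
        c = common(i, j)
        hist[c] = hist.get(c, 0) + 1
    return hist


def random_digraph(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    A = (rng.random((n, n)) < p).astype(int)
    np.fill_diagonal(A, 0)
    return A
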