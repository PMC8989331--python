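"""Dyad-independent exponential random graph models (ERGMs).

An ERGM places probability ``P(Y=y) ∝ exp(θ·g(y))`` on directed graphs,
where ``g`` is a vector of network statistics.  When every statistic is
*dyad-independent* — its change statistic ``δ_ij`` for toggling edge (i, j)
depends only on the attributes of i and j — the likelihood factorises over
ordered pairs into independent Bernoulli terms with

    p_ij = logistic(θ · δ_ij),

so maximum pseudo-likelihood estimation (MPLE, a logistic regression of the
edge indicator on the change statistics) coincides with exact maximum
likelihood, and networks can be simulated exactly by independent Bernoulli
draws per dyad.  This module implements that engine: term definitions and
change statistics, the full n(n−1) dyad design, Newton–Raphson MPLE with
Wald inference and AIC, bidirectional stepwise AIC selection, and exact
simulation.

Dyad-dependent terms (triangles, GWESP, …) require MCMC-MLE and are
deliberately unsupported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ErgmTerm",
    "DyadDesign",
    "ErgmModel",
    "UnsupportedTermError",
    "change_matrix",
    "build_design",
    "network_statistics",
    "fit_mple",
    "stepwise_select",
    "expand_candidates",
    "simulate_adjacency",
    "simulate_networks",
]

DYAD_INDEPENDENT_TERMS = frozenset(
    {
        "edges",
        "edgecov",
        "nodefactor",
        "nodeifactor",
        "nodeofactor",
        "nodematch",  # uniform homophily
        "nodematch_diff",  # differential homophily, one stat per level
        "nodemix",
    }
)


class UnsupportedTermError(ValueError):
    """Raised for terms whose change statistic depends on the rest of the graph."""


@dataclass(frozen=True)
class ErgmTerm:
    """One expanded network statistic.

    Parameters
    ----------
    term
        One of ``edges``, ``edgecov``, ``nodefactor``, ``nodeifactor``,
        ``nodeofactor``, ``nodematch``, ``nodematch_diff``, ``nodemix``.
    attribute
        Nodal attribute name (factor/match/mix terms) or edge covariate name
        (``edgecov``); ``None`` for ``edges``.
    level
        Attribute level identifying the statistic (factor and differential
        homophily terms) or an ordered ``(from, to)`` pair (``nodemix``).
    """

    term: str
    attribute: str | None = None
    level: object = None

    def __post_init__(self) -> None:
        if self.term not in DYAD_INDEPENDENT_TERMS:
            raise UnsupportedTermError(
                f"term {self.term!r} is not dyad-independent; MCMC-MLE is out of scope"
            )
        needs_level = self.term in {
            "nodefactor",
            "nodeifactor",
            "nodeofactor",
            "nodematch_diff",
            "nodemix",
        }
        if needs_level and self.level is None:
            raise ValueError(f"term {self.term!r} requires a level")
        if self.term == "nodemix" and (
            not isinstance(self.level, tuple) or len(self.level) != 2
        ):
            raise ValueError("nodemix level must be an ordered (from, to) pair")

    @property
    def label(self) -> str:
        if self.term == "edges":
            return "edges"
        if self.term == "edgecov":
            return f"edgecov.{self.attribute}"
        if self.term == "nodematch":
            return f"nodematch.{self.attribute}"
        if self.term == "nodemix":
            lf, lt = self.level  # type: ignore[misc]
            return f"nodemix.{self.attribute}.{lf}>{lt}"
        return f"{self.term}.{self.attribute}.{self.level}"


def change_matrix(
    term: ErgmTerm,
    attrs: pd.DataFrame,
    covariates: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """n×n matrix of change statistics δ_ij for every ordered pair.

    Row index is the origin i, column the destination j.  The diagonal is
    meaningless (self-loops are excluded downstream).
    """
    n = len(attrs)
    if term.term == "edges":
        return np.ones((n, n))
    if term.term == "edgecov":
        covariates = covariates or {}
        if term.attribute not in covariates:
            raise KeyError(f"edge covariate {term.attribute!r} not supplied")
        mat = np.asarray(covariates[term.attribute], dtype=float)
        if mat.shape != (n, n):
            raise ValueError(f"edge covariate must be {n}x{n}, got {mat.shape}")
        return mat
    a = attrs[term.attribute].to_numpy()
    if term.term == "nodefactor":
        ind = (a == term.level).astype(float)
        return ind[:, None] + ind[None, :]
    if term.term == "nodeifactor":
        ind = (a == term.level).astype(float)
        return np.broadcast_to(ind[None, :], (n, n)).copy()
    if term.term == "nodeofactor":
        ind = (a == term.level).astype(float)
        return np.broadcast_to(ind[:, None], (n, n)).copy()
    if term.term == "nodematch":
        return (a[:, None] == a[None, :]).astype(float)
    if term.term == "nodematch_diff":
        ind = a == term.level
        return (ind[:, None] & ind[None, :]).astype(float)
    if term.term == "nodemix":
        lf, lt = term.level  # type: ignore[misc]
        return ((a == lf)[:, None] & (a == lt)[None, :]).astype(float)
    raise UnsupportedTermError(term.term)


@dataclass
class DyadDesign:
    """Edge indicators and change statistics for all n(n−1) ordered pairs."""

    y: np.ndarray  # (n(n-1),) 0/1 edge indicator
    X: np.ndarray  # (n(n-1), k) change statistics
    terms: list[ErgmTerm]
    nodes: list
    aliased: list[int] = field(default_factory=list)  # exactly collinear columns

    _gram: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def gram(self) -> np.ndarray:
        if self._gram is None:
            self._gram = self.X.T @ self.X
        return self._gram

    def subset(self, cols: list[int]) -> "DyadDesign":
        gram = self.gram[np.ix_(cols, cols)]
        sub = DyadDesign(
            y=self.y,
            X=self.X[:, cols],
            terms=[self.terms[c] for c in cols],
            nodes=self.nodes,
            aliased=_find_aliased_gram(gram),
        )
        sub._gram = gram
        return sub


def _offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def _find_aliased_gram(G: np.ndarray) -> list[int]:
    """Columns exactly collinear with earlier columns, from the Gram matrix.

    rank(X[:, S]) equals rank(G[S, S]) for G = XᵀX, so the check runs on k×k
    submatrices rather than the full n(n−1)-row design.
    """
    k = G.shape[0]
    aliased: list[int] = []
    kept: list[int] = []
    for j in range(k):
        cols = kept + [j]
        sub = G[np.ix_(cols, cols)]
        if np.linalg.matrix_rank(sub) == len(cols):
            kept.append(j)
        else:
            aliased.append(j)
    return aliased


def build_design(
    adjacency: np.ndarray,
    attrs: pd.DataFrame,
    terms: list[ErgmTerm],
    covariates: dict[str, np.ndarray] | None = None,
) -> DyadDesign:
    """Assemble the full dyad design from a 0/1 adjacency matrix.

    ``attrs`` is indexed by node id in the same order as the adjacency rows.
    Exactly collinear columns are detected by a rank check and reported in
    ``DyadDesign.aliased``; they are left in place so callers can decide how
    to handle them.
    """
    A = np.asarray(adjacency)
    n = len(attrs)
    if A.shape != (n, n):
        raise ValueError(f"adjacency must be {n}x{n}, got {A.shape}")
    mask = _offdiag_mask(n)
    y = A[mask].astype(float)
    X = np.column_stack(
        [change_matrix(t, attrs, covariates)[mask] for t in terms]
    ) if terms else np.empty((n * (n - 1), 0))
    design = DyadDesign(y=y, X=X, terms=list(terms), nodes=list(attrs.index))
    design.aliased = _find_aliased_gram(design.gram)
    return design


def network_statistics(design: DyadDesign) -> np.ndarray:
    """Observed statistics g(y): for dyad-independent terms, Σ_dyads y·δ."""
    return design.X.T @ design.y


@dataclass
class ErgmModel:
    """A fitted (or ground-truth) dyad-independent ERGM."""

    terms: list[ErgmTerm]
    theta: np.ndarray
    loglik: float = np.nan
    aic: float = np.nan
    se: np.ndarray | None = None
    pvalues: np.ndarray | None = None
    converged: bool = True
    separation: bool = False
    n_dyads: int = 0

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.terms]

    def wald_interval(self, level: float = 0.95) -> np.ndarray:
        """(k, 2) array of Wald confidence limits."""
        z = stats.norm.ppf(0.5 + level / 2.0)
        se = self.se if self.se is not None else np.full_like(self.theta, np.nan)
        return np.column_stack([self.theta - z * se, self.theta + z * se])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.labels,
                "estimate": self.theta,
                "se": self.se,
                "p_value": self.pvalues,
            }
        )

    def to_dict(self) -> dict:
        return {
            "terms": [
                {"term": t.term, "attribute": t.attribute,
                 "level": list(t.level) if isinstance(t.level, tuple) else t.level}
                for t in self.terms
            ],
            "theta": self.theta.tolist(),
            "se": None if self.se is None else self.se.tolist(),
            "pvalues": None if self.pvalues is None else self.pvalues.tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "converged": self.converged,
            "separation": self.separation,
            "n_dyads": self.n_dyads,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "ErgmModel":
        terms = [
            ErgmTerm(
                t["term"],
                t.get("attribute"),
                tuple(t["level"]) if isinstance(t.get("level"), list) else t.get("level"),
            )
            for t in d["terms"]
        ]
        return cls(
            terms=terms,
            theta=np.asarray(d["theta"], dtype=float),
            se=None if d.get("se") is None else np.asarray(d["se"], dtype=float),
            pvalues=None if d.get("pvalues") is None else np.asarray(d["pvalues"]),
            loglik=d.get("loglik", np.nan),
            aic=d.get("aic", np.nan),
            converged=d.get("converged", True),
            separation=d.get("separation", False),
            n_dyads=d.get("n_dyads", 0),
        )

    @classmethod
    def from_json(cls, path) -> "ErgmModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


_P_CLAMP = 1e-12  # probability clamp inside the log-likelihood
_GRAD_TOL = 1e-8
_MAX_NEWTON = 100
_SEPARATION_THETA = 15.0  # |θ| beyond which a non-converged fit is flagged


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    p = np.clip(1.0 / (1.0 + np.exp(-eta)), _P_CLAMP, 1.0 - _P_CLAMP)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def fit_mple(design: DyadDesign) -> ErgmModel:
    """Maximise the logistic pseudo-likelihood by Newton–Raphson.

    For dyad-independent terms this *is* the exact maximum likelihood.
    Convergence requires the sup-norm of the score to fall below 1e-8 within
    100 iterations.  Standard errors come from the observed information;
    ``aic = 2k − 2·loglik``.  Complete separation (an unbounded likelihood,
    e.g. an empty graph driving the edges coefficient to −∞) is detected and
    flagged rather than reported as a finite estimate.
    """
    if design.aliased:
        raise ValueError(
            f"design has aliased columns {design.aliased}; remove them before fitting"
        )
    y, X = design.y, design.X
    k = X.shape[1]
    theta = np.zeros(k)
    converged = False
    for _ in range(_MAX_NEWTON):
        eta = X @ theta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - p)
        if np.max(np.abs(grad)) < _GRAD_TOL:
            converged = True
            break
        w = p * (1.0 - p)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        # dampen absurd steps that arise near separation
        snorm = np.max(np.abs(step))
        if snorm > 50.0:
            step *= 50.0 / snorm
        theta = theta + step

    # complete separation drives coefficients toward ±∞; the gradient can
    # still vanish numerically (p pinned at 0/1), so flag on magnitude
    separation = bool(k and np.max(np.abs(theta)) > _SEPARATION_THETA)
    eta = X @ theta
    ll = _loglik(y, eta)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = theta / se
    pvals = 2.0 * stats.norm.sf(np.abs(zval))
    return ErgmModel(
        terms=list(design.terms),
        theta=theta,
        loglik=ll,
        aic=2.0 * k - 2.0 * ll,
        se=se,
        pvalues=pvals,
        converged=converged,
        separation=separation,
        n_dyads=len(y),
    )


def expand_candidates(
    grid: dict[str, list[str]],
    attrs: pd.DataFrame,
    covariates: dict[str, np.ndarray] | None = None,
    drop_reference: bool = True,
) -> list[ErgmTerm]:
    """Expand a term × attribute grid into per-level candidate statistics.

    ``grid`` maps a term name to the attribute names it applies to, e.g.
    ``{"nodefactor": ["type", "company"], "nodematch": ["company"], ...}``.
    Factor terms (nodefactor / nodeifactor / nodeofactor) and differential
    homophily expand to one statistic per level; with ``drop_reference`` the
    most frequent level of the attribute is withheld as reference to avoid
    aliasing with the intercept.  ``nodemix`` expands to every ordered pair
    of observed levels.  ``edges`` is implicit in selection and not listed.
    """
    out: list[ErgmTerm] = []
    for term_name, attributes in grid.items():
        if term_name == "edges":
            continue
        if term_name == "edgecov":
            for name in attributes:
                out.append(ErgmTerm("edgecov", name))
            continue
        for attr in attributes:
            counts = attrs[attr].value_counts()
            levels = list(counts.index)
            if term_name == "nodematch":
                out.append(ErgmTerm("nodematch", attr))
                continue
            if term_name == "nodematch_diff":
                use = levels[1:] if drop_reference else levels
                out.extend(ErgmTerm("nodematch_diff", attr, lv) for lv in use)
                continue
            if term_name == "nodemix":
                out.extend(
                    ErgmTerm("nodemix", attr, (lf, lt))
                    for lf in levels
                    for lt in levels
                )
                continue
            use = levels[1:] if drop_reference else levels
            out.extend(ErgmTerm(term_name, attr, lv) for lv in use)
    return out


def stepwise_select(
    adjacency: np.ndarray,
    attrs: pd.DataFrame,
    candidates: list[ErgmTerm],
    covariates: dict[str, np.ndarray] | None = None,
    max_iter: int = 50,
) -> tuple[ErgmModel, pd.DataFrame]:
    """Bidirectional stepwise AIC selection over dyad-independent candidates.

    Starts from the edges-only model; forward passes add the single candidate
    giving the greatest AIC decrease, backward passes drop the selected term
    whose removal most decreases AIC, alternating until neither direction
    improves.  ``edges`` is always retained.  Candidates whose addition makes
    the design rank-deficient, or whose fit does not converge, are skipped.
    Ties in AIC are broken by candidate declaration order.

    Returns the final model and a trace with one row per evaluated model
    (pass number, action, candidate label, AIC, accepted flag).
    """
    all_terms = [ErgmTerm("edges")] + list(candidates)
    full = build_design(adjacency, attrs, all_terms, covariates)

    def fit_cols(cols: list[int]) -> ErgmModel | None:
        sub = full.subset(cols)
        if sub.aliased:
            return None
        try:
            model = fit_mple(sub)
        except (ValueError, np.linalg.LinAlgError):
            return None
        if not model.converged or model.separation:
            return None
        return model

    current_cols = [0]
    current = fit_cols(current_cols)
    if current is None:
        raise RuntimeError("edges-only model failed to fit")
    trace_rows = [
        {"pass": 0, "action": "init", "candidate": "edges",
         "aic": current.aic, "accepted": True}
    ]
    for it in range(1, max_iter + 1):
        improved = False
        # forward: try adding each remaining candidate
        best_add, best_add_aic = None, current.aic
        for j in range(1, len(all_terms)):
            if j in current_cols:
                continue
            cand = fit_cols(current_cols + [j])
            aic = np.inf if cand is None else cand.aic
            trace_rows.append(
                {"pass": it, "action": "add", "candidate": all_terms[j].label,
                 "aic": aic, "accepted": False}
            )
            if aic < best_add_aic - 1e-10:
                best_add, best_add_aic = j, aic
        if best_add is not None:
            current_cols = current_cols + [best_add]
            current = fit_cols(current_cols)
            trace_rows.append(
                {"pass": it, "action": "add", "candidate": all_terms[best_add].label,
                 "aic": current.aic, "accepted": True}
            )
            improved = True
        # backward: try dropping each selected term except edges
        best_drop, best_drop_aic = None, current.aic
        for j in current_cols:
            if j == 0:
                continue
            cols = [c for c in current_cols if c != j]
            cand = fit_cols(cols)
            aic = np.inf if cand is None else cand.aic
            trace_rows.append(
                {"pass": it, "action": "drop", "candidate": all_terms[j].label,
                 "aic": aic, "accepted": False}
            )
            if aic < best_drop_aic - 1e-10:
                best_drop, best_drop_aic = j, aic
        if best_drop is not None:
            current_cols = [c for c in current_cols if c != best_drop]
            current = fit_cols(current_cols)
            trace_rows.append(
                {"pass": it, "action": "drop", "candidate": all_terms[best_drop].label,
                 "aic": current.aic, "accepted": True}
            )
            improved = True
        if not improved:
            break
    return current, pd.DataFrame(trace_rows)


def dyad_probabilities(
    model: ErgmModel,
    attrs: pd.DataFrame,
    covariates: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """n×n matrix of edge probabilities p_ij = logistic(θ·δ_ij); zero diagonal."""
    n = len(attrs)
    eta = np.zeros((n, n))
    for t, th in zip(model.terms, model.theta):
        eta += th * change_matrix(t, attrs, covariates)
    P = 1.0 / (1.0 + np.exp(-eta))
    np.fill_diagonal(P, 0.0)
    return P


def simulate_adjacency(
    model: ErgmModel,
    attrs: pd.DataFrame,
    n_sims: int,
    seed: int,
    covariates: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Exact simulation: (n_sims, n, n) stack of independent Bernoulli draws."""
    P = dyad_probabilities(model, attrs, covariates)
    rng = np.random.default_rng(seed)
    draws = rng.random((n_sims, *P.shape)) < P[None, :, :]
    return draws.astype(np.int8)


def simulate_networks(
    model: ErgmModel,
    attrs: pd.DataFrame,
    n_sims: int,
    seed: int,
    covariates: dict[str, np.ndarray] | None = None,
) -> list:
    """Simulate ``n_sims`` directed graphs as networkx DiGraphs over ``attrs.index``."""
    import networkx as nx

    stacks = simulate_adjacency(model, attrs, n_sims, seed, covariates)
    nodes = list(attrs.index)
    graphs = []
    for A in stacks:
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        ii, jj = np.nonzero(A)
        g.add_edges_from((nodes[i], nodes[j]) for i, j in zip(ii, jj))
        graphs.append(g)
    return graphs
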