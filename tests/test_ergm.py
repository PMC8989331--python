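"""Change statistics, MPLE, stepwise AIC selection, exact simulation."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from swinenet.ergm import (
    DyadDesign,
    ErgmModel,
    ErgmTerm,
    UnsupportedTermError,
    build_design,
    change_matrix,
    expand_candidates,
    fit_mple,
    network_statistics,
    simulate_adjacency,
    stepwise_select,
)

from oracles import random_digraph


def _attrs(n, seed=0, companies=4, types=("NU", "FF", "FA", "FI")):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "farm_type": rng.choice(types, n),
            "company": rng.choice([f"C{i}" for i in range(companies)], n),
        },
        index=[f"h{i}" for i in range(n)],
    )


# --------------------------------------------------------- change statistics

def test_change_statistic_values():
    attrs = pd.DataFrame(
        {"company": ["c5", "c5", "c9"], "farm_type": ["FI", "FI", "FA"]},
        index=list("abc"),
    )
    cm = change_matrix(ErgmTerm("nodematch", "company"), attrs)
    assert cm[0, 1] == 1.0 and cm[0, 2] == 0.0

    mix = change_matrix(ErgmTerm("nodemix", "farm_type", ("NU", "FF")), attrs)
    assert mix.sum() == 0.0  # no NU→FF dyads exist among FA/FI farms

    nf = change_matrix(ErgmTerm("nodefactor", "farm_type", "FI"), attrs)
    assert nf[0, 1] == 2.0  # both endpoints carry the level
    assert nf[0, 2] == 1.0
    assert nf[2, 0] == 1.0

    nif = change_matrix(ErgmTerm("nodeifactor", "farm_type", "FA"), attrs)
    nof = change_matrix(ErgmTerm("nodeofactor", "farm_type", "FA"), attrs)
    assert nif[0, 2] == 1.0 and nif[2, 0] == 0.0
    assert nof[2, 0] == 1.0 and nof[0, 2] == 0.0


def test_edges_design_is_all_ones():
    attrs = _attrs(3)
    A = np.zeros((3, 3), dtype=int)
    design = build_design(A, attrs, [ErgmTerm("edges")])
    assert design.X.shape == (6, 1)
    assert (design.X == 1.0).all()


def test_full_nodemix_plus_edges_is_aliased():
    attrs = _attrs(20, seed=1, types=("A", "B"))
    A = random_digraph(np.random.default_rng(2), 20, 0.2)
    terms = [ErgmTerm("edges")] + [
        ErgmTerm("nodemix", "farm_type", (a, b)) for a in ("A", "B") for b in ("A", "B")
    ]
    design = build_design(A, attrs, terms)
    assert design.aliased  # the K^2 indicators sum to the intercept


def test_statistic_totals_match_direct_counts():
    rng = np.random.default_rng(3)
    for _ in range(30):
        n = int(rng.integers(4, 9))
        attrs = _attrs(n, seed=int(rng.integers(1e6)))
        A = random_digraph(rng, n, 0.4)
        terms = [
            ErgmTerm("edges"),
            ErgmTerm("nodematch", "company"),
            ErgmTerm("nodefactor", "farm_type", "FI"),
            ErgmTerm("nodeifactor", "farm_type", "FA"),
            ErgmTerm("nodemix", "farm_type", ("NU", "FF")),
        ]
        design = build_design(A, attrs, terms)
        g = network_statistics(design)
        ft = attrs["farm_type"].to_numpy()
        comp = attrs["company"].to_numpy()
        edges = [(i, j) for i in range(n) for j in range(n) if i != j and A[i, j]]
        assert g[0] == len(edges)
        assert g[1] == sum(comp[i] == comp[j] for i, j in edges)
        assert g[2] == sum((ft[i] == "FI") + (ft[j] == "FI") for i, j in edges)
        assert g[3] == sum(ft[j] == "FA" for i, j in edges)
        assert g[4] == sum(ft[i] == "NU" and ft[j] == "FF" for i, j in edges)


def test_dyad_dependent_term_raises():
    with pytest.raises(UnsupportedTermError):
        ErgmTerm("triangles")


# ------------------------------------------------------------------- MPLE

def test_edges_only_equals_logit_density():
    rng = np.random.default_rng(4)
    attrs = _attrs(10)
    A = np.zeros((10, 10), dtype=int)
    flat = rng.choice(90, size=30, replace=False)
    pairs = [(i, j) for i in range(10) for j in range(10) if i != j]
    for k in flat:
        A[pairs[k]] = 1
    model = fit_mple(build_design(A, attrs, [ErgmTerm("edges")]))
    assert model.theta[0] == pytest.approx(np.log(30 / 60), abs=1e-8)
    assert model.converged


def test_empty_graph_flags_separation():
    attrs = _attrs(8)
    model = fit_mple(build_design(np.zeros((8, 8), int), attrs, [ErgmTerm("edges")]))
    assert model.separation


def test_mple_matches_generic_optimizer():
    """On assorted designs the Newton fit must agree with an independent
    generic maximiser of the same logistic likelihood."""
    rng = np.random.default_rng(5)
    for trial in range(5):
        n = int(rng.integers(8, 15))
        attrs = _attrs(n, seed=trial)
        A = random_digraph(rng, n, 0.35)
        terms = [ErgmTerm("edges"), ErgmTerm("nodematch", "company"),
                 ErgmTerm("nodeofactor", "farm_type", "FA")]
        design = build_design(A, attrs, terms)
        if design.aliased:
            continue
        model = fit_mple(design)
        if not model.converged or model.separation:
            continue

        y, X = design.y, design.X

        def nll(theta):
            eta = X @ theta
            return -np.sum(y * eta - np.logaddexp(0.0, eta))

        res = optimize.minimize(nll, np.zeros(X.shape[1]), method="BFGS",
                                options={"gtol": 1e-10})
        assert model.loglik == pytest.approx(-res.fun, abs=1e-6)
        assert np.allclose(model.theta, res.x, atol=1e-4)


def test_likelihood_equations_hold_at_optimum():
    rng = np.random.default_rng(6)
    attrs = _attrs(30, seed=9)
    A = random_digraph(rng, 30, 0.15)
    terms = [ErgmTerm("edges"), ErgmTerm("nodematch", "company")]
    design = build_design(A, attrs, terms)
    model = fit_mple(design)
    p = 1.0 / (1.0 + np.exp(-(design.X @ model.theta)))
    score = design.X.T @ (design.y - p)
    assert np.all(np.abs(score) < 1e-6)


def test_aic_counts_all_coefficients():
    rng = np.random.default_rng(7)
    attrs = _attrs(15)
    A = random_digraph(rng, 15, 0.3)
    m1 = fit_mple(build_design(A, attrs, [ErgmTerm("edges")]))
    m2 = fit_mple(build_design(A, attrs, [ErgmTerm("edges"),
                                          ErgmTerm("nodematch", "company")]))
    assert m1.aic == pytest.approx(2 * 1 - 2 * m1.loglik)
    assert m2.aic == pytest.approx(2 * 2 - 2 * m2.loglik)


def test_fitting_aliased_design_refused():
    attrs = _attrs(12, types=("A", "B"))
    A = random_digraph(np.random.default_rng(8), 12, 0.3)
    terms = [ErgmTerm("edges")] + [
        ErgmTerm("nodemix", "farm_type", (a, b)) for a in ("A", "B") for b in ("A", "B")
    ]
    design = build_design(A, attrs, terms)
    with pytest.raises(ValueError):
        fit_mple(design)


# -------------------------------------------------------------- simulation

def test_zero_probability_model_simulates_empty():
    attrs = _attrs(10)
    model = ErgmModel(terms=[ErgmTerm("edges")], theta=np.array([-50.0]))
    sims = simulate_adjacency(model, attrs, 10, seed=1)
    assert sims.sum() == 0


def test_simulation_mean_edge_count_binomial():
    attrs = pd.DataFrame(index=[f"h{i}" for i in range(200)])
    theta = float(np.log(0.02 / 0.98))
    model = ErgmModel(terms=[ErgmTerm("edges")], theta=np.array([theta]))
    sims = simulate_adjacency(model, attrs, 1000, seed=2)
    counts = sims.sum(axis=(1, 2))
    expected = 0.02 * 200 * 199
    mc_se = counts.std() / np.sqrt(1000)
    assert abs(counts.mean() - expected) < 4 * mc_se


def test_fit_then_simulate_reproduces_statistics():
    """At the MLE the expected simulated statistics equal the observed ones
    (likelihood equations), so the ensemble mean must straddle them."""
    rng = np.random.default_rng(9)
    attrs = _attrs(60, seed=10)
    truth = ErgmModel(
        terms=[ErgmTerm("edges"), ErgmTerm("nodematch", "company")],
        theta=np.array([-2.5, 1.0]),
    )
    A = simulate_adjacency(truth, attrs, 1, seed=11)[0]
    design = build_design(A, attrs, truth.terms)
    model = fit_mple(design)
    g_obs = network_statistics(design)
    sims = simulate_adjacency(model, attrs, 400, seed=12)
    mask = ~np.eye(60, dtype=bool)
    sim_g = np.array([design.X.T @ S[mask].astype(float) for S in sims])
    se = sim_g.std(axis=0) / np.sqrt(400)
    assert np.all(np.abs(sim_g.mean(axis=0) - g_obs) < 4 * se + 1e-9)


def test_simulation_deterministic_under_seed():
    attrs = _attrs(20)
    model = ErgmModel(terms=[ErgmTerm("edges")], theta=np.array([-1.0]))
    a = simulate_adjacency(model, attrs, 3, seed=7)
    b = simulate_adjacency(model, attrs, 3, seed=7)
    assert (a == b).all()


# ---------------------------------------------------------------- stepwise

def test_stepwise_recovers_strong_homophily():
    rng = np.random.default_rng(13)
    attrs = _attrs(150, seed=14, companies=6)
    truth = ErgmModel(
        terms=[ErgmTerm("edges"), ErgmTerm("nodematch", "company")],
        theta=np.array([-3.5, 2.0]),
    )
    A = simulate_adjacency(truth, attrs, 1, seed=15)[0]
    candidates = expand_candidates(
        {"nodematch": ["company"], "nodeofactor": ["farm_type"],
         "nodeifactor": ["farm_type"]},
        attrs,
    )
    model, trace = stepwise_select(A, attrs, candidates)
    assert "nodematch.company" in model.labels
    accepted = trace[trace["accepted"]]
    assert (accepted["aic"].diff().dropna() <= 1e-9).all()


def test_stepwise_null_truth_mostly_selects_edges_only():
    """With no informative candidates, AIC keeps the edges-only model in the
    majority of replicates (each uninformative candidate has ≈ 16% chance of
    passing the AIC bar, so a handful of candidates usually all fail)."""
    rng = np.random.default_rng(18)
    n = 300
    attrs = pd.DataFrame(
        {
            "company": rng.choice(["C0", "C1", "C2"], n),
            "sector": rng.choice(["breeding", "growing"], n, p=[0.1, 0.9]),
        },
        index=[f"h{i}" for i in range(n)],
    )
    truth = ErgmModel(terms=[ErgmTerm("edges")], theta=np.array([-3.0]))
    candidates = [
        ErgmTerm("nodematch", "company"),
        ErgmTerm("nodeofactor", "sector", "breeding"),
        ErgmTerm("nodeifactor", "sector", "breeding"),
    ]
    edges_only = 0
    n_rep = 40
    for rep in range(n_rep):
        A = simulate_adjacency(truth, attrs, 1, seed=30_000 + rep)[0]
        model, _ = stepwise_select(A, attrs, candidates)
        if model.labels == ["edges"]:
            edges_only += 1
    assert edges_only > n_rep / 2, edges_only


def test_stepwise_trace_contains_all_evaluations():
    attrs = _attrs(40, seed=16)
    A = random_digraph(np.random.default_rng(17), 40, 0.1)
    candidates = expand_candidates({"nodematch": ["company"]}, attrs)
    model, trace = stepwise_select(A, attrs, candidates)
    assert {"pass", "action", "candidate", "aic", "accepted"} <= set(trace.columns)
    assert (trace["action"] == "add").any()


def test_model_json_round_trip(tmp_path):
    model = ErgmModel(
        terms=[ErgmTerm("edges"), ErgmTerm("nodemix", "farm_type", ("NU", "FF"))],
        theta=np.array([-2.0, 1.5]),
        loglik=-10.0, aic=24.0,
        se=np.array([0.1, 0.2]), pvalues=np.array([0.01, 0.05]),
    )
    path = tmp_path / "m.json"
    model.to_json(path)
    back = ErgmModel.from_json(path)
    assert back.labels == model.labels
    assert np.allclose(back.theta, model.theta)
    assert back.terms[1].level == ("NU", "FF")
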