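"""Fit a dyad-independent ERGM by MPLE and select terms by stepwise AIC.

The network is simulated from a known ground truth (sparse baseline +
within-company homophily), so you can see the estimator recover the
generating coefficients and the selection procedure find the right term.
"""

import numpy as np
import pandas as pd

from swinenet.ergm import (
    ErgmModel, ErgmTerm, build_design, expand_candidates, fit_mple,
    simulate_adjacency, stepwise_select,
)

rng = np.random.default_rng(7)
n = 200
attrs = pd.DataFrame(
    {
        "company": rng.choice([f"C{i}" for i in range(8)], n),
        "farm_type": rng.choice(["NU", "FA", "FF", "FI"], n, p=[0.05, 0.1, 0.45, 0.4]),
    },
    index=[f"h{i}" for i in range(n)],
)
truth = ErgmModel(
    terms=[ErgmTerm("edges"), ErgmTerm("nodematch", "company")],
    theta=np.array([-3.5, 2.0]),
)
A = simulate_adjacency(truth, attrs, 1, seed=8)[0]
print(f"simulated network: {n} nodes, {A.sum()} edges "
      f"(density {A.sum() / (n * (n - 1)):.4f})")

# refit the true terms: estimates should sit near (-3.5, 2.0)
model = fit_mple(build_design(A, attrs, truth.terms))
print(model.summary().round(3).to_string(index=False))

# stepwise selection from edges-only over a candidate grid
candidates = expand_candidates(
    {"nodematch": ["company"], "nodeofactor": ["farm_type"],
     "nodeifactor": ["farm_type"]}, attrs)
selected, trace = stepwise_select(A, attrs, candidates)
print(f"\nselected terms: {selected.labels}")
print(f"edges-only AIC {trace.iloc[0]['aic']:.1f} → selected AIC {selected.aic:.1f}")
# The homophily term is recovered and the AIC drops sharply; spurious
# candidates rarely survive the backward passes.
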