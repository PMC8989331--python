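# Methods

## Scope and model

`swinenet` analyses between-farm pig trade as a directed, unweighted contact
network.  Nodes are holdings active in a time window (at least one loading or
unloading event); an edge origin→destination exists when at least one
reconstructed shipment links the pair in that window.  Edge multiplicity and
head counts are deliberately discarded after reconstruction: the questions
the toolkit addresses — who trades with whom, and which holding covariates
drive tie formation — are binary-tie questions.

Tie formation is modelled with exponential random graph models restricted to
**dyad-independent** terms.  For a statistics vector *g* the ERGM is
P(Y = y) ∝ exp(θ·g(y)); when every component of *g* has a change statistic
δ_ij depending only on the attributes of i and j, the model factorises into
independent Bernoulli dyads with p_ij = logistic(θ·δ_ij).  Two consequences
are used throughout:

* **Estimation.** Maximum pseudo-likelihood (logistic regression of the edge
  indicator on the change statistics over all n(n−1) ordered pairs) *is* the
  exact maximum likelihood.  The fit is a damped Newton–Raphson on the
  logistic log-likelihood, converging when the score's sup-norm falls below
  1e-8 (cap 100 iterations); probabilities are clamped to [1e-12, 1−1e-12]
  inside the log-likelihood.  Standard errors come from the observed
  information, AIC = 2k − 2·loglik with k counting all coefficients
  including the edges intercept.  Complete separation (e.g. an empty graph)
  is flagged whenever any |θ̂| exceeds 15 log-odds; such fits are excluded
  from model selection.
* **Simulation.** Networks are simulated exactly — one independent Bernoulli
  draw per dyad — with no MCMC burn-in question.

Dyad-dependent terms (triangles, shared-partner weights) are rejected with
an explicit error; supporting them would require MCMC-MLE, which is out of
scope because the intended model family never needs it.

### Supported terms

`edges` (intercept); `edgecov` (a quantitative dyad covariate, here the
Euclidean inter-holding distance in km); `nodefactor` / `nodeifactor` /
`nodeofactor` (level counts at either / the receiving / the sending
endpoint); `nodematch` (uniform homophily); `nodematch_diff` (one homophily
statistic per level); `nodemix` (one statistic per ordered level pair).

Factor terms expand to one statistic per level **except the most frequent
level**, which is withheld as reference to avoid aliasing with the
intercept; this convention is a package choice and is configurable
(`drop_reference`).  `nodemix` expands to all ordered pairs; selecting the
complete pair set together with `edges` is exactly collinear, which the
design-matrix rank check reports (computed on the Gram matrix, so repeated
stepwise fits stay cheap).

### Stepwise selection

Bidirectional stepwise AIC starts from the edges-only model.  A forward pass
adds the single candidate with the largest AIC decrease; a backward pass
drops the selected term (never `edges`) whose removal most decreases AIC;
passes alternate until neither improves.  Candidates whose addition makes
the design rank-deficient, or whose fit fails to converge or separates, are
skipped (treated as AIC = ∞).  AIC ties break by candidate declaration
order.  The returned trace records every evaluated model, so the
non-increasing accepted-AIC property is auditable.

## Cleaning cascade

Raw transport logs are ordered loading/unloading events.  Removal reasons
are applied as sequential passes in a fixed precedence:
outside-window, international, direct sale / household slaughter / unmarked,
missing transport or holding id, unregistered holding, animal removal,
transport lacking a matched loading/unloading pair, overseas territory.
Each record is removed and tallied at most once, under the first matching
reason — this makes tallies reproducible and the cascade idempotent.

Duplicate registry rows resolve by keeping the most recent record per
holding id; distinct ids under one owner within 500 m merge under the
earliest-created id (sites farther apart are genuinely different holdings).

Movements are reconstructed per transport and animal category: events sort
by sequence index (date as tie-break); a transport whose sequence does not
start with a loading contributes nothing; each loading pairs with every
subsequent unloading at a different holding.  Head counts are carried on
movements but never used to constrain pairing — balancing loads against
unloads is under-determined in the raw format.  The movement takes the
loading date and the unloading head count.  A consistency rule table then
drops implausible (category, origin-type) pairs — barrows from
farrowing-only farms, piglets from finishing-only farms, growing pigs from
farrowers, sows from the fattening chain; the table is configurable.

## Nodal attributes

* **Adapted farm type** — nucleus/multiplier production status overrides the
  declared activity; otherwise the declared type is promoted to the smallest
  type covering every husbandry area with non-zero reported capacity
  (a finisher with a post-weaning area becomes a post-weaner/finisher, all
  three areas give farrow-to-finish; the unnamed repro+fattening combination
  also promotes to farrow-to-finish).
* **Sector** — breeding (MU/NU/BS) vs growing (everything else); boar
  stations are epidemiological dead ends and are dropped from model-bound
  networks.
* **Size** — within-type quartiles of a reference animal count (sow places
  if a farrowing area exists, else growing-pig places, else barrow places):
  below the 25th percentile small, at or above the 75th large, else regular.
  Quantiles use linear interpolation so the boundaries are bit-reproducible.
  Types with fewer than 4 holdings, or with degenerate (equal) quartiles,
  are all regular.
* **Batch-rearing system (BRS)** — the number of simultaneously reared
  batches, inferred from the modal gap in days between consecutive imports
  (zero gaps discarded, ties to the smallest gap): 33–42 d → 4 batches,
  24–32 → 5, 17–23 → 7, 10–16 → 10, 4–9 → 20, anything else
  unidentifiable; farms mapped to 10 or 20 with capacity below the type's
  small threshold are relabelled small.10 / small.20.  The band table
  follows standard French batch-management rhythms (≈5-weekly imports for a
  4-batch system down to weekly for 20 batches) and is configurable — the
  inference is a proxy, not a measurement, and the 7-batch band and the
  small threshold in particular are conventions, not claims.

## Descriptive indicators

Computed per network (window × subset): order and size; median in/out-degree
over nodes with non-zero degree of that direction; average betweenness
relative to its directed-graph maximum (n−1)(n−2); weakly and strongly
connected component counts; global transitivity of the undirected collapse
(direction ignored; undefined when no connected triples exist); density
m/n(n−1); diameter and average path length over **reachable ordered pairs
only** (unreachable pairs are ignored, not imputed — the common igraph
convention); degree assortativity as the Pearson correlation of total degree
at the endpoints of each directed edge; reciprocity (fraction of edges whose
reverse exists); the proportion of nodes whose average Jaccard
neighbourhood-similarity against all other nodes is zero (undirected
neighbourhoods; a node scores zero iff it shares no neighbour with anyone);
and the mean Euclidean edge length in km (switchable to the all-pairs
universe).  Degenerate inputs yield NaN, never a fabricated zero.

Three of these definitions are genuinely open — the degree variant for
assortativity, the Jaccard averaging universe, and the distance universe —
and are exposed as switches with the defaults above.

## Goodness of fit

Six structural statistics compare the observed network to an ensemble
simulated from a fitted model over the same node set: in-degree and
out-degree histograms, minimum geodesic distance histogram (with an
unreachable bin), the 16-class directed triad census, and edgewise /
dyadwise shared-partner histograms.  Shared partners are counted on the
undirected collapse (a partner is any holding adjacent to both endpoints,
direction ignored); the dyadwise universe is all unordered pairs.  Both
choices are switch-less defaults here because the directed variants answer a
different question than neighbourhood overlap.

The ensemble is summarised by 2.5/25/50/75/97.5 percentile envelopes per
bin; an observed bin is covered when it lies inside the central 95%
envelope.  The in-model statistics (one per term) are reported the same
way; for an exactly-fitted dyad-independent model their simulated means
equal the observed statistics in expectation (the likelihood equations).
Cross-validation repeats the comparison against networks observed in other
windows, simulating over each window's own node set.

The triad census is computed by packing each triple's six arc indicators
into a 6-bit code and classifying through a 64-entry lookup table (derived
once from the canonical single-triad classification); the tests verify it
against exhaustive per-triple enumeration.

## Synthetic data generator

The generator emulates the structure of a national movement database, not
its confidential content.  What it reproduces:

* the active-holding type mix reported for the French industry (finishers
  37.36%, farrow-to-finish 34.20%, post-weaner/finishers 14.58%, …,
  non-industry remainder 6.39%), drawn i.i.d.;
* company membership (default 70% of holdings in one of 20 companies),
  outdoor (10%) and insularity (1%) flags;
* area capacities consistent with each type's husbandry areas, lognormal
  at realistic scales (≈150 sow places, ≈900 post-weaning places, ≈700
  fattening places);
* uniform planar coordinates in a 1000 × 950 km box with Euclidean
  distances — real geodesy is intentionally not emulated, keeping the
  distance covariate exact;
* animal-category routing along the production chain: breeding herds ship
  sows, farrowing farms ship piglets, the rest of the growing chain ships
  growing pigs — so sub-network splits have non-trivial content and a
  zero-defect log passes the consistency filter untouched;
* ordered loading-before-unloading event pairs per transport, scheduled on
  each destination's import rhythm (7–35 days) — either a fixed number of
  transports per edge, or rhythmic shipping across the whole window
  (`cover_window`), which makes trade stationary between semesters and
  gives the BRS inference a real signal;
* configurable defect classes, at most one per transport, each tagged in a
  hidden `_defect` column: missing ids, international and overseas legs
  (both endpoints re-pointed to dedicated foreign/overseas registry rows so
  each removal reason's tally is exact), direct sales, animal removals,
  orphan events (loading record dropped), and type-inconsistent shipments.

What it does **not** emulate: demographic realism of herd sizes, seasonality
(pig trade is essentially non-seasonal), international volumes, or the true
generative process of the real network — the ground-truth ERGM used for
simulation is a modelling convenience (sparse baseline ≈1% density, strong
within-company homophily +2, extra nucleus→farrow-to-finish flow +1.5,
farrowers as senders +1).  Passing tests therefore demonstrate that the
pipeline is *correct under its own assumptions* and recovers known
structure; they say nothing about how well a dyad-independent ERGM fits any
particular real trade network.

## Test and experiment sizes

Experiments are sized to be decisive yet quick: oracle equivalence uses 500
random digraphs with n ≤ 8 against loop-based reference implementations;
parameter recovery uses 300 nodes (89,700 dyads) × 100 replicates and
demands ≥ 90% empirical coverage of 95% Wald intervals per term; selection
consistency uses 200 nodes × 100 replicates with a ~15-statistic candidate
grid and demands the informative statistic (|θ| = 2) in ≥ 95 of them;
goodness-of-fit calibration uses 120 nodes and 500 simulated networks.  The
pipeline demonstration defaults to 1000 holdings, a July–December window and
a compact candidate grid; all of these scale up by configuration.

## Known limitations

* MPLE standard errors are exact only because the model family is
  dyad-independent; adding dyad-dependent terms would invalidate both the
  estimator shortcut and the Wald inference, which is why they are refused
  rather than approximated.
* Stepwise AIC over many expanded levels is a greedy search; with hundreds
  of candidates it inherits the usual selection-noise caveats (the tests
  quantify this at the scale they run).
* The BRS attribute is an inference from import rhythms and inherits every
  caveat of modal-interval estimation on irregular data.
* Multi-stop transports emit the full loading × subsequent-unloading product
  per category; if the real pairing is constrained by head-count balance,
  movement counts (not binary networks) would differ.
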