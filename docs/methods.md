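# Methods

## Model and assumptions

A Boolean network is a set of named nodes, each holding a binary state and
updated by a logic rule of an ordered list of regulators. This package
analyzes such networks through the multilinear (pseudo-Boolean) extension
of each rule: inputs are treated as independent Bernoulli variables, and
the probability that the rule outputs 1 becomes a square-free multilinear
polynomial `f̂` on `[0,1]^k` that agrees with the rule on every binary
corner. All quantitative notions in the package — output bias, Taylor
orders, derivative magnitudes, order-truncated dynamics — are read off
`f̂`.

Key assumptions baked into the pipeline:

* **Synchronous updating.** All nodes update simultaneously. The exact and
  truncated simulators share this scheme, so MAE differences reflect rule
  approximation only, not scheduling.
* **Independent inputs.** The extension treats regulator states as
  independent probabilities at each evaluation; correlations between
  regulators enter only through the network dynamics itself.
* **Default center 1/2.** Taylor decompositions are taken at
  `p = (1/2, …, 1/2)` unless a center is given: it is the unbiased choice
  and makes the order-0 term the output bias. General centers are
  supported throughout (`decompose(f, p)`).

## Conventions

* **Row order.** Truth-table row `i` assigns the first-listed input the
  most significant bit of `i`. Regulator order in a rule is semantic and
  preserved through `.bnet`/JSON round trips.
* **Multi-index codes.** A derivative multi-index `α ∈ {0,1}^k` is coded
  with the same bit convention, so coefficient vectors align with truth
  tables.
* **Constant/source nodes.** A rule that is a bare constant (`x, 1`) is
  encoded as a k = 1 self-input node with a constant output column, so the
  whole pipeline sees only decomposable tables. Summaries count these
  nodes; benchmark reports include the count. Whether upstream frozen
  inputs are better modeled as self-copying was genuinely open; the
  self-copying constant keeps every node's update well defined and is
  flagged wherever it matters.
* **`.bnet` dialect.** `targets, factors` header; `&`, `|`, `!`,
  parentheses, constants `0`/`1`; `#` comments. XOR is written expanded
  (`(a & !b) | (!a & b)`), matching the common dialect. The writer emits
  rules in disjunctive normal form over the rows mapped to 1; an all-zero
  column is written as a contradiction naming every regulator so wiring
  survives a round trip.
* **Input cap.** Rules accept at most 16 inputs (65 536 rows); beyond
  that an explicit size error is raised. Published logical models of
  regulation rarely exceed in-degree ~10.

## Numerical choices

* **Decomposition.** Coefficients are computed by a per-axis tensor
  transform (`O(k·2^k)`), equivalent to mixed finite differences of `f̂`
  — for a multilinear polynomial the derivative over a coordinate subset
  is its alternating finite difference with the remaining coordinates held
  at the center. Both routes are implemented (`decompose` vs
  `partial_derivative`) and agree to machine precision; an independent
  symbolic-expansion oracle covers all three-input functions in the test
  suite. Coefficient vectors are stored densely for every k up to the cap
  (at most 512 KiB per node); `to_sparse(tol=1e-12)` provides a
  nonzero-only export.
* **Truncated evaluation** contracts the (order-masked) coefficient vector
  with `(x − p)` one coordinate at a time; at the full order this
  reproduces `f̂` exactly. Values are *not* clamped by the evaluator.
* **Clamping.** The truncated simulator resets states to the nearest
  boundary of [0,1] after every synchronous step. From binary starts, the
  full-order truncated dynamics are bit-identical to the Boolean dynamics:
  all intermediate quantities at center 1/2 are dyadic rationals, exact in
  binary floating point.
* **MAE** compares the *final* step of the two simulations (mean squared
  difference over initial states and nodes). A time-averaged variant over
  the whole trajectory is available via `SimulationConfig(time_average=True)`
  for sensitivity analysis.
* **Undefined percent changes.** If the unconstrained-ensemble MAE is 0 at
  some order (typically the exact order), PMAE and approximability are
  reported as `None`/NaN with a warning — never a division by zero.
* **Rounding of target biases.** Random tables with target bias `b` on `k`
  inputs contain exactly `round(b·2^k)` ones, rounding half up. Biases of
  real rules are multiples of `2^-k`, so the rounding is usually exact.
* **Statistics.** Welch's t-test (Satterthwaite degrees of freedom) and
  the variance F-test are both two-sided; raw pairwise p-values are
  reported by default with an optional Bonferroni flag. Model summary and
  spectrum standard deviations are population (ddof 0) values describing
  the set of nodes/terms at hand; the two-sample tests use sample
  variances (ddof 1).

## Nonlinearity spectra

For each order ℓ from 1 to the maximum in-degree, the spectrum pools
`|∂^α f̂(1/2)|` over every node with in-degree ≥ ℓ and every `α` with
`|α| = ℓ`, normalizing each term by the largest magnitude achievable by
*any* rule with that node's output bias,
`(min(p, ½) − max(p − ½, 0))·2^ℓ`. The bound is attainable order by order
but not necessarily at several orders simultaneously within one rule, so
normalized values are comparable across orders only in that per-order
sense. Zero-valued derivatives are pooled (a node "contains" every term
its in-degree allows), and raw terms are pooled across nodes rather than
averaging per-node means first — with heterogeneous in-degrees the two
differ, and pooling raw terms weights every derivative equally. Constant
nodes are excluded by default: every derivative of a constant rule is zero
and its normalization degenerates to 0/0, so a network of constants has an
empty spectrum; `include_constant_nodes=True` pools their terms as exact
zeros instead.

## Null ensembles

* **Constrained:** wiring kept exactly, each node's output column replaced
  by a uniform permutation of itself (bias conserved exactly, member by
  member). Differences from these nulls isolate the arrangement of a
  rule's ones — its nonlinearity structure.
* **Unconstrained:** per-node `(k, bias)` pairs bootstrap-resampled
  *jointly* from the source model (preserving the empirical coupling of
  in-degree and bias; a marginal mode is available via `joint=False`),
  wiring re-drawn uniformly with distinct regulators (self-loops allowed,
  no multi-edges), tables uniform at the resampled bias. The choice of
  per-node resampling and loop-free wiring was open; both are configurable
  where they matter and documented here.
* Member `i` is seeded from `(spec.seed, i)`, so individual members can be
  regenerated independently.

## Synthetic data

The random-network generator (`generate_random_model`) is the package's
test bed. Its defaults draw in-degrees uniformly from {1, …, 5} and output
biases uniformly from [0.1625, 0.65625] — the ranges spanned by the mean
in-degrees (≈1.2–4.9) and mean output biases of published biological
Boolean model collections — with uniformly random wiring and tables. What
it emulates: the first-order statistics (size, connectivity, bias) of
curated models. What it does not: canalization, redundancy, modularity,
degree correlations, and the strongly monotone character of real
regulatory rules. Tests passing on generated networks therefore validate
the *machinery* (decomposition, simulation, scoring, calibration of the
nulls), not biological claims; directional claims about rule classes are
tested on purpose-built networks (a monotone AND/OR ring versus a
copy-backbone with XOR leaves) where the expected sign of linear
approximability follows from the rules' Taylor structure.

## Problem sizes

Simulation-based tests and examples run at reduced scale — tens to
hundreds of initial states, tens to a hundred steps, ensembles of 10–20
members over networks of ~8–20 nodes — chosen so the statistical checks
(sign of approximability, null calibration within two standard errors,
monotone mean MAE across orders) are well resolved at desk scale. The full
protocol used for published model suites (1000 initial states, 500 steps,
100-member ensembles) is the library default (`SimulationConfig()`,
`EnsembleSpec(size=100)`).

## Known limitations

* MAE necessarily shrinks as orders accumulate; approximability compares
  *relative* shrinkage against nulls and can still be negative (XOR-rich
  networks), which is the framework's falsifiability handle.
* The exact simulator enumerates each rule's truth table; memory grows as
  `2^k` per node, which is why the in-degree cap exists.
* Attractor structure, asynchronous/stochastic updating and
  degree-preserving edge-swap nulls are out of scope.
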