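# booltaylor

Quantifying the **regulatory nonlinearity** of Boolean network models of
biochemical regulation — how much a node's inputs act jointly rather than
independently — and how well a network can be approximated when only the
lower orders of that nonlinearity are kept.

The package is aimed at systems biologists working with logical models of
gene regulation, signaling or disease pathways (e.g. BoolNet / Cell
Collective style rule files) who want to ask: *is the logic of this network
more, or less, linear than chance would predict?*

## The method

A Boolean rule `f : {0,1}^k → {0,1}` becomes a continuous pseudo-Boolean
function by treating each input as an independent Bernoulli variable with
success probability `p_i`:

    f̂(p₁, …, p_k) = Σ_{x ∈ R₁} Π_i p̂_i ,    p̂_i = p_i if x_i = 1 else 1 − p_i,

where `R₁` is the set of input states mapped to 1. `f̂` is the unique
multilinear polynomial agreeing with `f` on every binary corner, and
`f̂(1/2, …, 1/2)` is the output bias of `f`. Because `f̂` is square-free,
its Taylor expansion about a center `p` is finite:

    f̂(x) = Σ_{α ∈ {0,1}^k} ∂^α f̂(p) · (x − p)^α .

The order `|α|` groups terms by how many inputs interact; order 0 is the
constant bias, order 1 the linear part, order k the exact rule. Truncating
every node's expansion at order *m* and iterating the resulting continuous
map (states clamped to [0,1], synchronous updates) gives the **order-m
approximation** of the network. The quality of that approximation is the

* **MAE** — mean squared difference between exact Boolean and truncated
  continuous states at the end of the simulation, over shared random
  initial states;
* **PMAE** — percent change of a MAE relative to the MAE of an
  *unconstrained* random ensemble (node count kept, per-node in-degree and
  bias bootstrap-resampled, wiring re-drawn);
* **approximability** — `PMAE(constrained ensemble) − PMAE(model)`, where
  the *constrained* ensemble keeps the model's wiring and per-node bias and
  only shuffles the logic. Positive approximability at order 1 ("linear
  approximability") means the model's rules are easier to linearize than
  bias- and wiring-matched random logic.

Per-order **nonlinearity spectra** report the mean absolute Taylor
derivative of each order, normalized by the largest magnitude any rule with
that output bias could achieve, `(min(p, ½) − max(p − ½, 0)) · 2^{|α|}`.

## Worked example

A 3-node network using all three 2-input gate types — `a ← ¬b`,
`b ← a ∨ c`, `c ← a ⊕ b`:

```sh
printf 'targets, factors\na, !b\nb, a | c\nc, (a & !b) | (!a & b)\n' > demo3.bnet
booltaylor --out-dir out spectrum demo3.bnet
```

```
 order  mean       sd  n
     1   0.6 0.489898  5
     2   1.0 0.000000  2
```

Order 1 pools five normalized first-order derivatives: 1 (NOT), 1, 1 (OR)
and 0, 0 — the XOR node has *no* linear content, which is what makes XOR
non-monotone. Both second-order terms are maximal for their biases.

```sh
booltaylor --out-dir out benchmark demo3.bnet --orders 0,1,2 \
    --ensemble-size 20 --n-init 200 --steps 100 --seed 1
```

```
model  order  mae_model  mae_constrained  mae_unconstrained  pmae_model  pmae_constrained  approximability
demo3      0   0.230000         0.229750           0.237583   -3.191863         -3.297089        -0.105226
demo3      1   0.223519         0.166631           0.094414  136.742581         76.489863       -60.252718
demo3      2   0.000000         0.000000           0.000000         NaN               NaN              NaN
```

At order 1 this little network has approximability −60: it is markedly
*harder* to linearize than its rule-shuffled nulls, because the XOR node's
first-order truncation is no better than its constant bias. At order 2 the
truncation is exact (MAE 0 for the model and both ensembles, so percent
changes are undefined and reported as NaN/None). Identical seeds give
bit-identical reports.

The same pipeline is available from Python (`booltaylor.benchmark`,
`booltaylor.spectrum`, …) for scripting larger studies.

## Reproducing published suite statistics

No network models are bundled. To reproduce suite-level results for the
publicly available collections of logical models of biochemical regulation
(Cell Collective and similar repositories), export each model to `.bnet`
text, then for each model run `booltaylor benchmark <model>.bnet` with the
full protocol (`--ensemble-size 100 --n-init 1000 --steps 500`), collect
the per-model `linear_approximability` values into a TSV, attach category
labels in a sidecar TSV (`model`, `C1`, `C2` columns) and compare groups
with `booltaylor categories`. Per-model wall time grows with node count and
in-degree; the exact truncation order range is chosen automatically from
each model's in-degrees.

## Layout

| module | contents |
| --- | --- |
| `booltaylor.boolfunc` | truth tables, rule-expression parsing, multilinear extension, output bias |
| `booltaylor.taylor` | Taylor derivatives/decompositions, truncated evaluation, derivative bound, spectra |
| `booltaylor.network_io` | network container, `.bnet`/JSON I/O, random-network generator, summaries |
| `booltaylor.ensembles` | constrained (rule-shuffled) and unconstrained (bootstrap) null ensembles |
| `booltaylor.dynamics` | exact and truncated synchronous simulation, MAE/PMAE/approximability |
| `booltaylor.analysis`, `booltaylor.cli` | Welch t-test, variance F-test, category reports; command-line interface |

See `docs/methods.md` for modeling assumptions, conventions and numerical
choices.
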