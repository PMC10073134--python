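"""Boolean network container, `.bnet` / JSON readers and writers, and the
synthetic random-network generator.

The `.bnet` dialect accepted here is the common BoolNet text format: a
``targets, factors`` header, one ``node, expression`` line per node,
``&``/``|``/``!``/parentheses/``0``/``1`` in expressions, ``#`` comments.
Regulator order within a rule is semantic — it fixes the truth-table bit
order (first regulator = most significant bit) — and is preserved on a
read/write round trip.

Constant (source) nodes are encoded uniformly as k = 1 nodes wired to
themselves with a constant output column, so every node has a decomposable
truth table; reports flag them as constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .boolfunc import (
    MAX_INPUTS,
    ExpressionError,
    TruthTable,
    state_bits,
    truth_table_from_expression,
)

__all__ = [
    "BooleanNetworkModel",
    "ModelSummary",
    "BnetParseError",
    "read_bnet",
    "write_bnet",
    "read_truth_table_json",
    "write_truth_table_json",
    "read_category_labels",
    "generate_random_model",
    "default_indegree_sampler",
    "default_bias_sampler",
    "summarize",
]

C1_CATEGORIES = ("biochemical", "signaling", "disease", "metabolic", "regulatory")
C2_CATEGORIES = ("metazoan", "cancer", "primitive", "plants")


@dataclass(frozen=True)
class BooleanNetworkModel:
    """A named Boolean network: nodes, wiring and per-node truth tables.

    ``inputs[node]`` lists the regulators of ``node`` in truth-table bit
    order; ``tables[node]`` is the matching :class:`TruthTable` with
    ``k == len(inputs[node])``.  ``metadata`` carries free-form provenance
    plus the optional pathway-ontology category labels ``category_C1``
    (biochemical / signaling / disease / metabolic / regulatory) and
    ``category_C2`` (metazoan / cancer / primitive / plants).
    """

    nodes: tuple[str, ...]
    inputs: dict[str, tuple[str, ...]]
    tables: dict[str, TruthTable]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        declared = set(self.nodes)
        if len(declared) != len(self.nodes):
            raise ValueError("duplicate node names")
        object.__setattr__(self, "inputs", dict(self.inputs))
        for node in self.nodes:
            if node not in self.inputs or node not in self.tables:
                raise ValueError(f"node {node!r} missing inputs or table")
            regs = tuple(self.inputs[node])
            for r in regs:
                if r not in declared:
                    raise ValueError(f"node {node!r} has undeclared regulator {r!r}")
            if len(regs) < 1:
                raise ValueError(
                    f"node {node!r} has in-degree 0; encode constants as "
                    "self-input nodes with a constant table"
                )
            if self.tables[node].k != len(regs):
                raise ValueError(
                    f"node {node!r}: table has {self.tables[node].k} inputs "
                    f"but {len(regs)} regulators are declared"
                )
            self.inputs[node] = regs

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def max_indegree(self) -> int:
        return max(t.k for t in self.tables.values())

    def is_constant_node(self, node: str) -> bool:
        out = self.tables[node].outputs
        return bool((out == out[0]).all())


@dataclass(frozen=True)
class ModelSummary:
    """Deterministic per-model aggregate statistics."""

    name: str
    n_nodes: int
    mean_indegree: float
    sd_indegree: float
    mean_bias: float
    sd_bias: float
    node_stats: tuple[tuple[str, int, float], ...]  # (node, k, bias)
    n_constant_nodes: int

    def to_row(self) -> dict:
        return {
            "model": self.name,
            "n_nodes": self.n_nodes,
            "mean_indegree": self.mean_indegree,
            "sd_indegree": self.sd_indegree,
            "mean_bias": self.mean_bias,
            "sd_bias": self.sd_bias,
            "n_constant_nodes": self.n_constant_nodes,
        }


def summarize(model: BooleanNetworkModel) -> ModelSummary:
    """Node count, in-degree and output-bias moments (population sd)."""
    ks = np.array([model.tables[n].k for n in model.nodes], dtype=np.float64)
    biases = np.array([model.tables[n].bias for n in model.nodes], dtype=np.float64)
    return ModelSummary(
        name=str(model.metadata.get("name", "")),
        n_nodes=model.n_nodes,
        mean_indegree=float(ks.mean()),
        sd_indegree=float(ks.std()),
        mean_bias=float(biases.mean()),
        sd_bias=float(biases.std()),
        node_stats=tuple(
            (n, model.tables[n].k, model.tables[n].bias) for n in model.nodes
        ),
        n_constant_nodes=sum(model.is_constant_node(n) for n in model.nodes),
    )


class BnetParseError(ValueError):
    """Malformed `.bnet` input, with a line number in the message."""


def _strip_comment(line: str) -> str:
    return line.split("#", 1)[0].strip()


def read_bnet(path: str | Path, name: str | None = None) -> BooleanNetworkModel:
    """Read a BoolNet-style `.bnet` rule file into a network model.

    Expects a ``targets, factors`` header followed by one
    ``target, expression`` line per node.  Regulator order is the order of
    first appearance in the expression.  Rules without identifiers
    (constants ``0``/``1``) become self-input constant nodes.

    Raises
    ------
    BnetParseError
        On a missing header, duplicate targets, undeclared regulators or
        expression syntax errors; messages carry the offending line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    entries: list[tuple[int, str, str]] = []
    header_seen = False
    for lineno, raw in enumerate(lines, start=1):
        line = _strip_comment(raw)
        if not line:
            continue
        if not header_seen:
            head = [part.strip().lower() for part in line.split(",")]
            if head[:2] != ["targets", "factors"]:
                raise BnetParseError(
                    f"{path.name}:{lineno}: expected 'targets, factors' header, "
                    f"got {line!r}"
                )
            header_seen = True
            continue
        if "," not in line:
            raise BnetParseError(
                f"{path.name}:{lineno}: expected 'target, expression', got {line!r}"
            )
        target, expr = line.split(",", 1)
        target = target.strip()
        expr = expr.strip()
        if not target or not expr:
            raise BnetParseError(f"{path.name}:{lineno}: empty target or expression")
        entries.append((lineno, target, expr))
    if not header_seen:
        raise BnetParseError(f"{path.name}: missing 'targets, factors' header")

    targets = [t for _, t, _ in entries]
    if len(set(targets)) != len(targets):
        dupes = sorted({t for t in targets if targets.count(t) > 1})
        raise BnetParseError(f"{path.name}: duplicate target(s) {dupes}")
    declared = set(targets)

    inputs: dict[str, tuple[str, ...]] = {}
    tables: dict[str, TruthTable] = {}
    for lineno, target, expr in entries:
        try:
            table = truth_table_from_expression(expr)
        except (ExpressionError, ValueError) as err:
            raise BnetParseError(f"{path.name}:{lineno}: {err}") from err
        if table.k == 0:
            # constant rule: encode as self-input with a constant column
            value = int(table.outputs[0])
            table = TruthTable(
                k=1,
                outputs=np.array([value, value], dtype=np.uint8),
                input_names=(target,),
            )
            inputs[target] = (target,)
        else:
            assert table.input_names is not None
            missing = [r for r in table.input_names if r not in declared]
            if missing:
                raise BnetParseError(
                    f"{path.name}:{lineno}: undeclared regulator(s) {missing} "
                    f"in rule for {target!r}"
                )
            inputs[target] = table.input_names
        tables[target] = table

    meta = {"name": name or path.stem, "source": str(path)}
    return BooleanNetworkModel(
        nodes=tuple(targets), inputs=inputs, tables=tables, metadata=meta
    )


def _rule_dnf(regs: Sequence[str], table: TruthTable) -> str:
    """Disjunctive normal form of a rule over its R1 rows.

    The all-zero column, which has an empty R1, is written as a
    contradiction mentioning every regulator in order so that the wiring
    and bit order survive a round trip.
    """
    k = table.k
    r1 = table.r1
    if r1.size == 0:
        return " | ".join(f"({r} & !{r})" for r in regs)
    bits = state_bits(k)
    terms = []
    for code in r1:
        lits = [
            reg if bit else f"!{reg}"
            for reg, bit in zip(regs, bits[code])
        ]
        terms.append("(" + " & ".join(lits) + ")" if k > 1 else lits[0])
    return " | ".join(terms)


def write_bnet(model: BooleanNetworkModel, path: str | Path) -> None:
    """Write a model as a `.bnet` file (rules in DNF over their R1 rows).

    Round-trip safe: :func:`read_bnet` of the output reproduces every
    truth table and regulator order bit-exactly.
    """
    path = Path(path)
    lines = ["targets, factors"]
    for node in model.nodes:
        lines.append(f"{node}, {_rule_dnf(model.inputs[node], model.tables[node])}")
    path.write_text("\n".join(lines) + "\n")


def write_truth_table_json(model: BooleanNetworkModel, path: str | Path) -> None:
    """Write a model as explicit truth-table JSON (documented row order)."""
    payload = {
        "name": model.metadata.get("name", ""),
        "nodes": [
            {
                "name": node,
                "inputs": list(model.inputs[node]),
                "outputs": [int(v) for v in model.tables[node].outputs],
            }
            for node in model.nodes
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_truth_table_json(path: str | Path) -> BooleanNetworkModel:
    """Read a model from the explicit truth-table JSON layout."""
    payload = json.loads(Path(path).read_text())
    inputs: dict[str, tuple[str, ...]] = {}
    tables: dict[str, TruthTable] = {}
    nodes = []
    for entry in payload["nodes"]:
        node = entry["name"]
        regs = tuple(entry["inputs"])
        nodes.append(node)
        inputs[node] = regs
        tables[node] = TruthTable(
            k=len(regs),
            outputs=np.asarray(entry["outputs"], dtype=np.uint8),
            input_names=regs,
        )
    meta = {"name": payload.get("name", Path(path).stem), "source": str(path)}
    return BooleanNetworkModel(
        nodes=tuple(nodes), inputs=inputs, tables=tables, metadata=meta
    )


def read_category_labels(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a sidecar TSV of per-model category labels.

    Layout: a header line ``model<TAB>C1<TAB>C2`` followed by one row per
    model.  Unknown category values raise; empty cells are allowed.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty label file")
    header = [h.strip() for h in lines[0].split("\t")]
    if header[:1] != ["model"]:
        raise ValueError(f"{path}: first column must be 'model', got {header}")
    out: dict[str, dict[str, str]] = {}
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        cells = [c.strip() for c in raw.split("\t")]
        row = dict(zip(header, cells))
        model = row.pop("model")
        c1 = row.get("C1", "")
        c2 = row.get("C2", "")
        if c1 and c1 not in C1_CATEGORIES:
            raise ValueError(f"{path}:{lineno}: unknown C1 category {c1!r}")
        if c2 and c2 not in C2_CATEGORIES:
            raise ValueError(f"{path}:{lineno}: unknown C2 category {c2!r}")
        out[model] = {"C1": c1, "C2": c2}
    return out


def random_table_with_bias(
    k: int, bias: float, rng: np.random.Generator, input_names=None
) -> TruthTable:
    """Uniform random truth table with exactly round(bias * 2^k) ones.

    Rounding is half-up, so a target bias that is a multiple of 2^-k is hit
    exactly.
    """
    if not 0.0 <= bias <= 1.0:
        raise ValueError("bias must lie in [0, 1]")
    n_rows = 2**k
    n_ones = int(np.floor(bias * n_rows + 0.5))
    outputs = np.zeros(n_rows, dtype=np.uint8)
    if n_ones > 0:
        outputs[rng.choice(n_rows, size=n_ones, replace=False)] = 1
    return TruthTable(k=k, outputs=outputs, input_names=input_names)


def default_indegree_sampler(rng: np.random.Generator) -> int:
    """Uniform in-degree on {1, ..., 5} (mean 3, within the 1.2–4.9 range of
    mean in-degrees typical of published biological Boolean models)."""
    return int(rng.integers(1, 6))


def default_bias_sampler(rng: np.random.Generator) -> float:
    """Uniform output bias on [0.1625, 0.65625], the range spanned by the
    mean output biases of published biological Boolean models."""
    return float(rng.uniform(0.1625, 0.65625))


def generate_random_model(
    n_nodes: int,
    indegree_sampler: Callable[[np.random.Generator], int] | int = default_indegree_sampler,
    bias_sampler: Callable[[np.random.Generator], float] | float = default_bias_sampler,
    seed: int | np.random.SeedSequence = 0,
    name: str | None = None,
) -> BooleanNetworkModel:
    """Generate a random Boolean network with sampled in-degrees and biases.

    Each node draws an in-degree ``k`` and a target output bias ``b``, picks
    ``k`` distinct regulators uniformly (self-loops permitted) and receives
    a uniform random table with exactly ``round(b * 2^k)`` ones.  Fully
    reproducible from ``seed``.

    ``indegree_sampler`` / ``bias_sampler`` may be callables taking the
    generator, or plain constants.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    rng = np.random.default_rng(seed)
    k_of = indegree_sampler if callable(indegree_sampler) else (lambda _rng: indegree_sampler)
    b_of = bias_sampler if callable(bias_sampler) else (lambda _rng: bias_sampler)
    node_names = tuple(f"n{i}" for i in range(n_nodes))
    inputs: dict[str, tuple[str, ...]] = {}
    tables: dict[str, TruthTable] = {}
    for node in node_names:
        k = int(k_of(rng))
        if k < 1:
            raise ValueError("indegree sampler must yield k >= 1")
        if k > min(n_nodes, MAX_INPUTS):
            raise ValueError(
                f"sampled in-degree {k} exceeds min(n_nodes, cap) = "
                f"{min(n_nodes, MAX_INPUTS)}"
            )
        bias = float(b_of(rng))
        regs = tuple(node_names[j] for j in rng.choice(n_nodes, size=k, replace=False))
        inputs[node] = regs
        tables[node] = random_table_with_bias(k, bias, rng, input_names=regs)
    meta = {"name": name or f"random-{n_nodes}", "source": "generate_random_model"}
    return BooleanNetworkModel(
        nodes=node_names, inputs=inputs, tables=tables, metadata=meta
    )
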