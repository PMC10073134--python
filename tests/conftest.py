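"""Shared fixtures: basic gates, the 3-node demo network, synthetic network
builders and the independent symbolic Taylor oracle."""

from __future__ import annotations

import numpy as np
import pytest

from booltaylor import TruthTable, truth_table_from_expression
from booltaylor.network_io import BooleanNetworkModel


@pytest.fixture(scope="session")
def gates() -> dict[str, TruthTable]:
    return {
        "AND": truth_table_from_expression("x1 & x2"),
        "OR": truth_table_from_expression("x1 | x2"),
        "XOR": truth_table_from_expression("(x1 & !x2) | (!x1 & x2)"),
        "NOT": truth_table_from_expression("!x"),
    }


def build_demo3_model() -> BooleanNetworkModel:
    """3-node network using NOT, OR and XOR: a <- !b, b <- a|c, c <- a xor b."""
    rules = {
        "a": "!b",
        "b": "a | c",
        "c": "(a & !b) | (!a & b)",
    }
    inputs, tables = {}, {}
    for node, rule in rules.items():
        t = truth_table_from_expression(rule)
        inputs[node] = t.input_names
        tables[node] = t
    return BooleanNetworkModel(
        nodes=("a", "b", "c"), inputs=inputs, tables=tables,
        metadata={"name": "demo3"},
    )


@pytest.fixture()
def demo3() -> BooleanNetworkModel:
    return build_demo3_model()


def build_xor_rich_model(n_backbone: int = 6, n_leaves: int = 6) -> BooleanNetworkModel:
    """Copy-node backbone ring driving XOR leaf nodes.

    The leaves have zero first-order Taylor terms, so the order-1 dynamics
    of the model itself cannot track them, while bias-preserving rule
    shuffles turn most leaves into copy-like (linear) rules.
    """
    nodes = tuple(
        [f"b{i}" for i in range(n_backbone)] + [f"x{i}" for i in range(n_leaves)]
    )
    inputs: dict[str, tuple[str, ...]] = {}
    tables: dict[str, TruthTable] = {}
    for i in range(n_backbone):
        reg = (f"b{(i + 1) % n_backbone}",)
        inputs[f"b{i}"] = reg
        tables[f"b{i}"] = truth_table_from_expression(reg[0], input_names=reg)
    for i in range(n_leaves):
        regs = (f"b{i % n_backbone}", f"b{(i + 1) % n_backbone}")
        inputs[f"x{i}"] = regs
        tables[f"x{i}"] = truth_table_from_expression(
            "({0} & !{1}) | (!{0} & {1})".format(*regs), input_names=regs
        )
    return BooleanNetworkModel(
        nodes=nodes, inputs=inputs, tables=tables, metadata={"name": "xor-rich"}
    )


def build_monotone_model(n_nodes: int = 12) -> BooleanNetworkModel:
    """Ring of 3-input monotone AND/OR rules: n_i <- (n_{i+1} & n_{i+2}) | n_{i+3}.

    Monotone rules concentrate Taylor weight at low orders; bias-preserving
    shuffles of their tables are typically more nonlinear, so the model
    should be *more* linearly approximable than its constrained nulls.
    """
    nodes = tuple(f"n{i}" for i in range(n_nodes))
    inputs: dict[str, tuple[str, ...]] = {}
    tables: dict[str, TruthTable] = {}
    for i, v in enumerate(nodes):
        regs = tuple(nodes[(i + d) % n_nodes] for d in (1, 2, 3))
        inputs[v] = regs
        tables[v] = truth_table_from_expression(
            "({0} & {1}) | {2}".format(*regs), input_names=regs
        )
    return BooleanNetworkModel(
        nodes=nodes, inputs=inputs, tables=tables, metadata={"name": "monotone"}
    )


def random_truth_table(k: int, rng: np.random.Generator) -> TruthTable:
    return TruthTable(k=k, outputs=rng.integers(0, 2, size=2**k).astype(np.uint8))


def sympy_taylor_coeffs(table: TruthTable, p=None) -> np.ndarray:
    """Independent symbolic oracle for Taylor coefficients.

    Expands the R1-sum polynomial symbolically, re-centers it at ``p`` by
    substituting ``x_j = y_j + p_j``, and reads off the monomial
    coefficients of ``y^alpha``.  Returns the length-2^k coefficient vector
    in multi-index-code order (input 0 = most significant bit).
    """
    import sympy as sp

    k = table.k
    if p is None:
        p = [sp.Rational(1, 2)] * k
    else:
        p = [sp.nsimplify(v, rational=True) for v in p]
    xs = sp.symbols(f"x0:{k}")
    ys = sp.symbols(f"y0:{k}")
    f = sp.Integer(0)
    for code in range(2**k):
        if not table.outputs[code]:
            continue
        term = sp.Integer(1)
        for j in range(k):
            bit = (code >> (k - 1 - j)) & 1
            term *= xs[j] if bit else (1 - xs[j])
        f += term
    f = sp.expand(f.subs({xs[j]: ys[j] + p[j] for j in range(k)}, simultaneous=True))
    poly = sp.Poly(f, *ys)
    coeffs = np.zeros(2**k)
    for code in range(2**k):
        mono = tuple((code >> (k - 1 - j)) & 1 for j in range(k))
        coeffs[code] = float(poly.coeff_monomial(mono))
    return coeffs
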