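"""Taylor decomposition: worked examples, symbolic oracle, truncation,
derivative bound and nonlinearity spectra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from booltaylor import (
    TruthTable,
    decompose,
    eval_truncated,
    extension_eval,
    max_abs_derivative,
    partial_derivative,
    spectrum,
    truth_table_from_expression,
)
from booltaylor.network_io import BooleanNetworkModel

from conftest import build_demo3_model, random_truth_table, sympy_taylor_coeffs

EXPECTED_DECOMPOSITIONS = {
    # multi-index tuple -> derivative value at center (1/2, 1/2)
    "AND": {(0, 0): 0.25, (0, 1): 0.5, (1, 0): 0.5, (1, 1): 1.0},
    "OR": {(0, 0): 0.75, (0, 1): 0.5, (1, 0): 0.5, (1, 1): -1.0},
    "XOR": {(0, 0): 0.5, (0, 1): 0.0, (1, 0): 0.0, (1, 1): -2.0},
    "NOT": {(0,): 0.5, (1,): -1.0},
}


@pytest.mark.parametrize("gate", sorted(EXPECTED_DECOMPOSITIONS))
def test_decomposition_worked_examples(gates, gate):
    got = dict(decompose(gates[gate]).items())
    assert got == pytest.approx(EXPECTED_DECOMPOSITIONS[gate], abs=1e-15)


@pytest.mark.parametrize(
    "gate, alpha, expected",
    [
        ("XOR", (1, 1), -2.0),
        ("XOR", (1, 0), 0.0),
        ("XOR", (0, 1), 0.0),
        ("AND", (1, 0), 0.5),
        ("OR", (1, 1), -1.0),
        ("NOT", (1,), -1.0),
    ],
)
def test_partial_derivative_worked_examples(gates, gate, alpha, expected):
    assert partial_derivative(gates[gate], alpha) == pytest.approx(expected, abs=1e-15)


def test_partial_derivative_agrees_with_decompose_at_general_center():
    """Dual route: corner-by-corner finite differences match the tensor
    transform at an off-center expansion point."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        k = int(rng.integers(1, 5))
        t = random_truth_table(k, rng)
        p = rng.uniform(0.1, 0.9, size=k)
        d = decompose(t, p)
        for code in range(2**k):
            alpha = tuple((code >> (k - 1 - j)) & 1 for j in range(k))
            assert partial_derivative(t, alpha, p) == pytest.approx(
                d.coefficient(alpha), abs=1e-12
            )


def test_symbolic_oracle_k2_exhaustive_and_k3_sampled():
    """Finite-difference coefficients equal the symbolic re-centered
    polynomial coefficients, at the default and at a general center."""
    for code in range(16):
        t = TruthTable(k=2, outputs=np.array([(code >> i) & 1 for i in range(4)]))
        np.testing.assert_allclose(
            decompose(t).coeffs, sympy_taylor_coeffs(t), atol=1e-12
        )
    rng = np.random.default_rng(19)
    p = (0.3, 0.7, 0.25)
    for _ in range(12):
        t = random_truth_table(3, rng)
        np.testing.assert_allclose(
            decompose(t, p).coeffs, sympy_taylor_coeffs(t, p), atol=1e-12
        )


def test_constant_and_order0_terms():
    d = decompose(truth_table_from_expression("1", input_names=("a", "b")))
    assert d.coeffs[0] == 1.0
    assert np.all(d.coeffs[1:] == 0.0)
    or_d = decompose(truth_table_from_expression("x1 | x2"))
    assert or_d.coeffs[0] == 0.75  # order-0 term is the output bias


@pytest.mark.parametrize(
    "gate, x, max_order, expected",
    [
        ("OR", (0.1, 0.9), 0, 0.75),  # order 0 is the constant bias
        ("OR", (0.0, 0.0), 0, 0.75),
        ("XOR", (1.0, 1.0), 1, 0.5),  # XOR has no first-order terms
        ("OR", (1.0, 0.0), 2, 1.0),  # exact order reproduces the corner
    ],
)
def test_eval_truncated_worked_examples(gates, gate, x, max_order, expected):
    d = decompose(gates[gate])
    assert eval_truncated(d, x, max_order) == pytest.approx(expected, abs=1e-15)


def test_eval_truncated_full_order_is_exact():
    """max_order >= k reproduces the multilinear extension everywhere."""
    rng = np.random.default_rng(31)
    for _ in range(8):
        k = int(rng.integers(1, 5))
        t = random_truth_table(k, rng)
        d = decompose(t)
        xs = rng.uniform(0, 1, size=(125, k))
        got = eval_truncated(d, xs, k)
        expected = np.array([extension_eval(t, x) for x in xs])
        np.testing.assert_allclose(got, expected, atol=1e-12)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(k=st.integers(1, 4), table_code=st.integers(0, 2**16 - 1), data=st.data())
def test_full_order_truncation_reconstructs_extension(k, table_code, data):
    """Property: the complete decomposition reproduces f_hat at any point."""
    outputs = np.array([(table_code >> i) & 1 for i in range(2**k)], dtype=np.uint8)
    t = TruthTable(k=k, outputs=outputs)
    x = data.draw(st.lists(st.floats(0, 1, allow_nan=False), min_size=k, max_size=k))
    d = decompose(t)
    assert eval_truncated(d, x, k) == pytest.approx(
        extension_eval(t, x), abs=1e-12
    )


def test_eval_truncated_is_not_clamped(gates):
    # OR truncated to order 1 at (1, 1) gives 1.25: clamping is the
    # simulator's job, not the evaluator's
    d = decompose(gates["OR"])
    assert eval_truncated(d, (1.0, 1.0), 1) == pytest.approx(1.25, abs=1e-15)


@pytest.mark.parametrize(
    "bias, order, expected",
    [(0.5, 2, 2.0), (0.25, 2, 1.0), (0.0, 3, 0.0), (1.0, 1, 0.0), (0.5, 1, 1.0)],
)
def test_max_abs_derivative_values(bias, order, expected):
    assert max_abs_derivative(bias, order) == pytest.approx(expected, abs=1e-15)


def test_max_abs_derivative_rejects_order_zero():
    with pytest.raises(ValueError):
        max_abs_derivative(0.5, 0)


def test_bound_holds_and_is_attained_k2():
    """Exhaustive over the 16 two-input functions: every derivative respects
    the bias-dependent bound, and for each (bias, order) some function
    attains it (e.g. XOR attains 2 at bias 1/2, order 2)."""
    best: dict[tuple[float, int], float] = {}
    for code in range(16):
        t = TruthTable(k=2, outputs=np.array([(code >> i) & 1 for i in range(4)]))
        d = decompose(t)
        orders = d.orders
        for level in (1, 2):
            bound = max_abs_derivative(t.bias, level)
            vals = np.abs(d.coeffs[orders == level])
            assert (vals <= bound + 1e-12).all()
            key = (t.bias, level)
            best[key] = max(best.get(key, 0.0), float(vals.max()))
    for (bias, level), achieved in best.items():
        assert achieved == pytest.approx(max_abs_derivative(bias, level), abs=1e-12)


def test_monotone_gates_have_linear_terms_xor_does_not(gates):
    for gate in ("AND", "OR"):
        d = decompose(gates[gate])
        assert all(abs(d.coefficient(a)) > 0 for a in [(1, 0), (0, 1)])
    xd = decompose(gates["XOR"])
    assert xd.coefficient((1, 0)) == 0.0 and xd.coefficient((0, 1)) == 0.0


def _single_function_model(expr: str, n_regs: int) -> BooleanNetworkModel:
    """Network where every node applies ``expr`` to the next nodes around a ring."""
    nodes = tuple(f"n{i}" for i in range(max(n_regs + 1, 2)))
    inputs, tables = {}, {}
    for i, v in enumerate(nodes):
        regs = tuple(nodes[(i + d) % len(nodes)] for d in range(1, n_regs + 1))
        inputs[v] = regs
        tables[v] = truth_table_from_expression(
            expr.format(*regs), input_names=regs
        )
    return BooleanNetworkModel(
        nodes=nodes, inputs=inputs, tables=tables, metadata={"name": "single"}
    )


def test_spectrum_xor_only_network():
    model = _single_function_model("({0} & !{1}) | (!{0} & {1})", 2)
    spec = spectrum(model)
    assert spec.mean(1) == 0.0  # XOR: zero first-order content
    assert spec.mean(2) == pytest.approx(1.0)  # |-2| / bound(1/2, 2) = 1
    assert sorted(spec.orders) == [1, 2]


def test_spectrum_constant_network_is_empty():
    nodes = ("a", "b")
    tables = {
        n: truth_table_from_expression("1", input_names=(n,)) for n in nodes
    }
    model = BooleanNetworkModel(
        nodes=nodes, inputs={n: (n,) for n in nodes}, tables=tables,
        metadata={"name": "const"},
    )
    assert spectrum(model).orders == {}
    # opt-in: constants pooled as exact zeros
    inc = spectrum(model, include_constant_nodes=True)
    assert inc.orders == {1: (0.0, 0.0, 2)}


def test_spectrum_demo3_by_hand():
    """NOT/OR/XOR network: order-1 terms are 1 (NOT), 1, 1 (OR), 0, 0 (XOR)
    after normalization; order-2 terms are 1 (OR) and 1 (XOR)."""
    spec = spectrum(build_demo3_model())
    assert spec.count(1) == 5 and spec.count(2) == 2
    assert spec.mean(1) == pytest.approx(0.6)
    assert spec.sd(1) == pytest.approx(np.std([1, 1, 1, 0, 0]))
    assert spec.mean(2) == pytest.approx(1.0)
    assert spec.sd(2) == 0.0


def test_spectrum_export_rows():
    rows = spectrum(build_demo3_model()).to_rows()
    assert [r[0] for r in rows] == [1, 2]
    assert all(len(r) == 4 for r in rows)


def test_sparse_export(gates):
    sparse = decompose(gates["XOR"]).to_sparse()
    assert sparse == {(0, 0): 0.5, (1, 1): -2.0}
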