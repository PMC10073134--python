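"""Boolean functions as truth tables and their multilinear probabilistic extension.

A Boolean function ``f : {0,1}^k -> {0,1}`` is stored as an explicit output
vector over all ``2^k`` input states.  Treating each input as an independent
Bernoulli variable with success probability ``p_i`` turns ``f`` into a
continuous pseudo-Boolean function

    f_hat(p) = sum_{x in R1} prod_i p_hat_i,

where ``R1`` is the set of input states mapped to 1 and ``p_hat_i = p_i`` if
``x_i = 1`` else ``1 - p_i``.  ``f_hat`` is the unique multilinear polynomial
agreeing with ``f`` on every binary corner; its value at
``p = (1/2, ..., 1/2)`` is the output bias ``|R1| / 2^k``.

Row-order convention (used by every routine in this package): state code
``i`` in ``[0, 2^k)`` assigns input ``j`` (counting from 0) the bit of ``i``
with place value ``2^(k-1-j)``; i.e. the *first-listed input is the most
significant bit*, so rows run (0,...,0), (0,...,1), ..., (1,...,1).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MAX_INPUTS",
    "TruthTable",
    "ExpressionError",
    "truth_table_from_expression",
    "extension_eval",
    "output_bias",
    "state_bits",
]

#: Hard cap on the number of inputs of a single rule (2^16 table rows).
MAX_INPUTS = 16


def state_bits(k: int) -> np.ndarray:
    """Return the ``(2^k, k)`` binary state matrix in the package row order.

    Column 0 (the first input) is the most significant bit of the row code.
    """
    if k == 0:
        return np.zeros((1, 0), dtype=np.uint8)
    codes = np.arange(2**k, dtype=np.int64)
    shifts = np.arange(k - 1, -1, -1)
    return ((codes[:, None] >> shifts[None, :]) & 1).astype(np.uint8)


@dataclass(frozen=True)
class TruthTable:
    """A k-input Boolean function as an explicit output vector.

    Parameters
    ----------
    k:
        Number of inputs (``>= 0``).
    outputs:
        Length ``2^k`` vector with values in ``{0, 1}``, indexed by the
        state code described in the module docstring.
    input_names:
        Optional ordered labels for the inputs.
    """

    k: int
    outputs: np.ndarray
    input_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be non-negative")
        if self.k > MAX_INPUTS:
            raise ValueError(
                f"truth table with {self.k} inputs exceeds the cap of "
                f"{MAX_INPUTS} (2^{self.k} rows)"
            )
        out = np.asarray(self.outputs, dtype=np.uint8)
        if out.ndim != 1 or out.shape[0] != 2**self.k:
            raise ValueError(
                f"outputs must have length 2^{self.k} = {2 ** self.k}, "
                f"got shape {out.shape}"
            )
        if not np.isin(out, (0, 1)).all():
            raise ValueError("outputs must be 0/1 valued")
        out.setflags(write=False)
        object.__setattr__(self, "outputs", out)
        if self.input_names is not None:
            names = tuple(self.input_names)
            if len(names) != self.k:
                raise ValueError("input_names length must equal k")
            object.__setattr__(self, "input_names", names)

    @property
    def r1(self) -> np.ndarray:
        """State codes mapped to 1."""
        return np.flatnonzero(self.outputs == 1)

    @property
    def r0(self) -> np.ndarray:
        """State codes mapped to 0."""
        return np.flatnonzero(self.outputs == 0)

    @property
    def bias(self) -> float:
        """Output bias ``|R1| / 2^k`` (exact dyadic rational)."""
        return int(self.outputs.sum()) / 2**self.k

    def __call__(self, state: Sequence[int]) -> int:
        """Evaluate the Boolean function at a binary input state."""
        bits = np.asarray(state, dtype=np.int64)
        if bits.shape != (self.k,):
            raise ValueError(f"state must have length {self.k}")
        code = 0
        for b in bits:
            code = (code << 1) | int(b)
        return int(self.outputs[code])


class ExpressionError(ValueError):
    """Malformed or out-of-contract rule expression."""


_TOKEN_RE = re.compile(r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_.]*)|(?P<op>[!&|()])|(?P<const>[01]))")


def _tokenize(expr: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            if expr[pos:].strip() == "":
                break
            raise ExpressionError(
                f"unexpected character {expr[pos:].strip()[0]!r} in rule {expr!r}"
            )
        if m.group("name"):
            tokens.append(("name", m.group("name")))
        elif m.group("op"):
            tokens.append(("op", m.group("op")))
        else:
            tokens.append(("const", m.group("const")))
        pos = m.end()
    return tokens


def _reduce(op, funcs, env):
    acc = funcs[0](env)
    for f in funcs[1:]:
        acc = op(acc, f(env))
    return acc


class _Parser:
    """Recursive-descent parser for the `&`, `|`, `!` rule grammar.

    Produces a closure evaluating the expression on a dict of numpy bit
    columns, plus the identifiers in order of first appearance.
    """

    def __init__(self, tokens: list[tuple[str, str]], expr: str):
        self.tokens = tokens
        self.pos = 0
        self.expr = expr
        self.names: list[str] = []

    def peek(self) -> tuple[str, str] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> tuple[str, str]:
        tok = self.peek()
        if tok is None:
            raise ExpressionError(f"unexpected end of rule {self.expr!r}")
        self.pos += 1
        return tok

    def parse(self):
        node = self.parse_or()
        if self.peek() is not None:
            raise ExpressionError(
                f"trailing tokens after position {self.pos} in rule {self.expr!r}"
            )
        return node

    def parse_or(self):
        terms = [self.parse_and()]
        while self.peek() == ("op", "|"):
            self.take()
            terms.append(self.parse_and())
        if len(terms) == 1:
            return terms[0]
        return lambda env, fs=tuple(terms): _reduce(np.bitwise_or, fs, env)

    def parse_and(self):
        factors = [self.parse_factor()]
        while self.peek() == ("op", "&"):
            self.take()
            factors.append(self.parse_factor())
        if len(factors) == 1:
            return factors[0]
        return lambda env, fs=tuple(factors): _reduce(np.bitwise_and, fs, env)

    def parse_factor(self):
        kind, value = self.take()
        if kind == "op" and value == "!":
            inner = self.parse_factor()
            return lambda env, f=inner: 1 - f(env)
        if kind == "op" and value == "(":
            inner = self.parse_or()
            closing = self.take()
            if closing != ("op", ")"):
                raise ExpressionError(f"expected ')' in rule {self.expr!r}")
            return inner
        if kind == "const":
            return lambda env, c=np.uint8(int(value)): c
        if kind == "name":
            if value not in self.names:
                self.names.append(value)
            return lambda env, n=value: env[n]
        raise ExpressionError(f"unexpected token {value!r} in rule {self.expr!r}")


def truth_table_from_expression(
    expr: str, input_names: Sequence[str] | None = None
) -> TruthTable:
    """Compile a rule expression into a :class:`TruthTable`.

    The grammar supports identifiers, ``&`` (AND), ``|`` (OR), ``!`` (NOT),
    parentheses and the constants ``0``/``1``.  ``|`` binds loosest, then
    ``&``, then ``!``.

    Parameters
    ----------
    expr:
        Rule text, e.g. ``"(a & !b) | c"``.
    input_names:
        Ordered input labels fixing the truth-table bit order.  When omitted,
        identifiers are taken in order of first appearance in ``expr``.  Every
        identifier in ``expr`` must be listed; extra names are allowed and
        become non-essential inputs.

    Raises
    ------
    ExpressionError
        On malformed expressions or identifiers missing from ``input_names``.
    ValueError
        When the input count exceeds :data:`MAX_INPUTS`.
    """
    parser = _Parser(_tokenize(expr), expr)
    evaluate = parser.parse()
    if input_names is None:
        names = tuple(parser.names)
    else:
        names = tuple(input_names)
        unknown = [n for n in parser.names if n not in names]
        if unknown:
            raise ExpressionError(
                f"unknown identifier(s) {unknown} in rule {expr!r}; "
                f"declared inputs are {list(names)}"
            )
    k = len(names)
    if k > MAX_INPUTS:
        raise ValueError(
            f"rule {expr!r} has {k} inputs, exceeding the cap of {MAX_INPUTS}"
        )
    bits = state_bits(k)
    env = {name: bits[:, j] for j, name in enumerate(names)}
    outputs = np.broadcast_to(np.asarray(evaluate(env), dtype=np.uint8), (2**k,))
    return TruthTable(k=k, outputs=outputs.copy(), input_names=names)


def extension_eval(f: TruthTable, p: Sequence[float]) -> float:
    """Evaluate the multilinear extension ``f_hat`` at probability vector ``p``.

    Computes the sum over ``R1`` of the Bernoulli state probabilities
    ``prod_i p_hat_i``; the result is a probability in ``[0, 1]`` and agrees
    with the Boolean output at every binary corner.
    """
    pv = np.asarray(p, dtype=np.float64)
    if pv.shape != (f.k,):
        raise ValueError(f"p must have length {f.k}, got shape {pv.shape}")
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if f.k == 0:
        return float(f.outputs[0])
    bits = state_bits(f.k)[f.r1]
    if bits.shape[0] == 0:
        return 0.0
    probs = np.where(bits == 1, pv[None, :], 1.0 - pv[None, :])
    return float(probs.prod(axis=1).sum())


def output_bias(f: TruthTable) -> float:
    """Fraction of input states mapped to 1; equals ``f_hat`` at p = 1/2."""
    return f.bias
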