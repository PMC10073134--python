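"""Taylor decomposition of multilinear Boolean-function extensions.

Because the extension ``f_hat`` of a k-input Boolean function is a
square-free multilinear polynomial, its Taylor expansion about any center
``p`` in ``[0,1]^k`` is finite:

    f_hat(x) = sum_{alpha} d^alpha f_hat(p) * (x - p)^alpha,

with the sum over all 2^k binary multi-indices ``alpha`` (``alpha! = 1``
throughout since no variable is differentiated twice).  The order-0 term is
``f_hat(p)`` — the output bias of ``f`` when ``p = (1/2, ..., 1/2)``, the
default center everywhere in this package.  Truncating the sum to
``|alpha| <= m`` gives the order-m approximation: order 0 is the constant
bias, order 1 is linear, order k is exact.

Multi-index codes use the same convention as truth-table rows: the bit of
code ``a`` with place value ``2^(k-1-j)`` is ``alpha_j`` for input ``j``, so
``popcount(a) = |alpha|``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterator, Sequence

import numpy as np

from .boolfunc import TruthTable, extension_eval, state_bits

if TYPE_CHECKING:  # pragma: no cover
    from .network_io import BooleanNetworkModel

__all__ = [
    "TaylorDecomposition",
    "NonlinearitySpectrum",
    "partial_derivative",
    "decompose",
    "eval_truncated",
    "max_abs_derivative",
    "spectrum",
]


def _orders(k: int) -> np.ndarray:
    """|alpha| for every multi-index code 0 .. 2^k - 1."""
    codes = np.arange(2**k, dtype=np.uint32)
    return np.array([int(c).bit_count() for c in codes], dtype=np.int64)


@dataclass(frozen=True)
class TaylorDecomposition:
    """Finite Taylor expansion of a multilinear extension about a center.

    Attributes
    ----------
    k:
        Number of inputs.
    center:
        The expansion center ``p`` (length ``k``).
    coeffs:
        Length ``2^k`` vector of derivative values ``d^alpha f_hat(p)``,
        indexed by multi-index code; entry 0 is ``f_hat(p)``.
    input_names:
        Optional input labels inherited from the truth table.
    """

    k: int
    center: np.ndarray
    coeffs: np.ndarray
    input_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        center = np.asarray(self.center, dtype=np.float64)
        coeffs = np.asarray(self.coeffs, dtype=np.float64)
        if center.shape != (self.k,):
            raise ValueError("center must have length k")
        if coeffs.shape != (2**self.k,):
            raise ValueError("coeffs must have length 2^k")
        center.setflags(write=False)
        coeffs.setflags(write=False)
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "coeffs", coeffs)

    @property
    def orders(self) -> np.ndarray:
        """|alpha| per coefficient slot."""
        return _orders(self.k)

    def coefficient(self, alpha: Sequence[int]) -> float:
        """Derivative value for a multi-index given as a 0/1 sequence."""
        a = np.asarray(alpha, dtype=np.int64)
        if a.shape != (self.k,) or not np.isin(a, (0, 1)).all():
            raise ValueError(f"alpha must be a binary vector of length {self.k}")
        code = 0
        for bit in a:
            code = (code << 1) | int(bit)
        return float(self.coeffs[code])

    def items(self) -> Iterator[tuple[tuple[int, ...], float]]:
        """Iterate (alpha tuple, derivative value) over all 2^k entries."""
        bits = state_bits(self.k)
        for code in range(2**self.k):
            yield tuple(int(b) for b in bits[code]), float(self.coeffs[code])

    def to_sparse(self, tol: float = 1e-12) -> dict[tuple[int, ...], float]:
        """Nonzero entries only, as a dict keyed by alpha tuple."""
        return {a: v for a, v in self.items() if abs(v) > tol}

    def truncated_coeffs(self, max_order: int) -> np.ndarray:
        """Coefficient vector with entries of order > ``max_order`` zeroed."""
        out = self.coeffs.copy()
        out[self.orders > max_order] = 0.0
        return out


def partial_derivative(
    f: TruthTable, alpha: Sequence[int], p: Sequence[float] | None = None
) -> float:
    """Mixed partial derivative ``d^alpha f_hat`` evaluated at center ``p``.

    For a multilinear polynomial the mixed derivative over the coordinates in
    ``alpha`` is the alternating-sign finite difference over those
    coordinates, with the remaining coordinates held at ``p`` — equivalently
    a weighted average of corner differences with weights given by the
    Bernoulli probabilities of the non-differentiated coordinates.  At
    ``p = (1/2, ..., 1/2)`` (the default) the weights are uniform,
    ``1 / 2^(k - |alpha|)``.

    This routine goes through :func:`booltaylor.boolfunc.extension_eval`
    corner by corner; :func:`decompose` computes all coefficients at once by
    a tensor transform, and the two agree to machine precision.
    """
    a = np.asarray(alpha, dtype=np.int64)
    if a.shape != (f.k,) or not np.isin(a, (0, 1)).all():
        raise ValueError(f"alpha must be a binary vector of length {f.k}")
    pv = (
        np.full(f.k, 0.5)
        if p is None
        else np.asarray(p, dtype=np.float64)
    )
    if pv.shape != (f.k,):
        raise ValueError(f"p must have length {f.k}")
    idx = np.flatnonzero(a == 1)
    m = idx.size
    total = 0.0
    for corner in range(2**m):
        point = pv.copy()
        ones = 0
        for pos, j in enumerate(idx):
            bit = (corner >> (m - 1 - pos)) & 1
            point[j] = float(bit)
            ones += bit
        sign = 1.0 if (m - ones) % 2 == 0 else -1.0
        total += sign * extension_eval(f, point)
    return total


def decompose(f: TruthTable, p: Sequence[float] | None = None) -> TaylorDecomposition:
    """Full Taylor decomposition of ``f_hat`` about center ``p``.

    Uses a per-coordinate tensor transform: writing each corner-interpolation
    factor as ``a_j + b_j (x_j - p_j)`` with ``a_j = p_j`` or ``1 - p_j`` and
    ``b_j = +/-1`` depending on the corner bit, the coefficient of
    ``(x - p)^alpha`` is obtained by applying the 2x2 matrix
    ``[[1 - p_j, p_j], [-1, 1]]`` along each coordinate axis of the output
    tensor.  Runs in ``O(k 2^k)``.
    """
    k = f.k
    pv = np.full(k, 0.5) if p is None else np.asarray(p, dtype=np.float64)
    if pv.shape != (k,):
        raise ValueError(f"p must have length {k}")
    c = f.outputs.astype(np.float64)
    if k == 0:
        return TaylorDecomposition(k=0, center=pv, coeffs=c, input_names=f.input_names)
    c = c.reshape((2,) * k)
    for axis in range(k):
        c0 = np.take(c, 0, axis=axis)
        c1 = np.take(c, 1, axis=axis)
        value = (1.0 - pv[axis]) * c0 + pv[axis] * c1  # alpha_j = 0: evaluate at p_j
        deriv = c1 - c0  # alpha_j = 1: finite difference
        c = np.stack([value, deriv], axis=axis)
    return TaylorDecomposition(
        k=k, center=pv, coeffs=c.reshape(-1), input_names=f.input_names
    )


def eval_truncated(
    d: TaylorDecomposition, x: Sequence[float] | np.ndarray, max_order: int
) -> float | np.ndarray:
    """Evaluate the order-``max_order`` truncation of a decomposition at ``x``.

    ``x`` may be a single length-k point or an ``(n, k)`` batch.  The result
    is *not* clamped to [0, 1]; range restriction is the simulator's job.
    ``max_order >= k`` reproduces the exact extension value.
    """
    if max_order < 0:
        raise ValueError("max_order must be non-negative")
    xv = np.asarray(x, dtype=np.float64)
    single = xv.ndim == 1
    if single:
        xv = xv[None, :]
    if xv.shape[1] != d.k:
        raise ValueError(f"x must have {d.k} columns")
    coeffs = d.truncated_coeffs(max_order)
    result = _fold_eval(coeffs, xv - d.center[None, :])
    return float(result[0]) if single else result


def _fold_eval(coeffs: np.ndarray, diffs: np.ndarray) -> np.ndarray:
    """Horner-style contraction of a coefficient vector with (x - p) columns.

    ``coeffs`` has length 2^k (multi-index codes, input 0 = MSB); ``diffs``
    is ``(n, k)``.  Returns the length-n polynomial values.
    """
    n, k = diffs.shape
    c = np.broadcast_to(coeffs, (n, coeffs.shape[0]))
    for j in range(k):
        half = c.shape[1] // 2
        c = c[:, :half] + diffs[:, j : j + 1] * c[:, half:]
    return c[:, 0]


def max_abs_derivative(bias: float, order: int) -> float:
    """Largest possible |Taylor derivative| of the given order at p = 1/2.

    For a Boolean function with output bias ``b``, every derivative of order
    ``|alpha| >= 1`` taken at the center (1/2, ..., 1/2) satisfies

        |d^alpha f_hat| <= (min(b, 1/2) - max(b - 1/2, 0)) * 2^|alpha|,

    with equality attainable for each order separately (not necessarily for
    several orders simultaneously within one function).  Used to normalize
    nonlinearity spectra across nodes and models.
    """
    if order < 1:
        raise ValueError("order must be >= 1 (the bound is stated for |alpha| >= 1)")
    if not 0.0 <= bias <= 1.0:
        raise ValueError("bias must lie in [0, 1]")
    return (min(bias, 0.5) - max(bias - 0.5, 0.0)) * 2.0**order


@dataclass(frozen=True)
class NonlinearitySpectrum:
    """Per-order normalized Taylor-derivative magnitudes of a network.

    ``orders`` maps each order with at least one contributing node to the
    (mean, standard deviation, term count) of the pooled normalized
    magnitudes.  Orders exceeding every node's in-degree are absent, not
    zero.
    """

    orders: dict[int, tuple[float, float, int]]

    def mean(self, order: int) -> float:
        return self.orders[order][0]

    def sd(self, order: int) -> float:
        return self.orders[order][1]

    def count(self, order: int) -> int:
        return self.orders[order][2]

    def max_order(self) -> int:
        return max(self.orders) if self.orders else 0

    def to_rows(self) -> list[tuple[int, float, float, int]]:
        """(order, mean, sd, n) rows sorted by order, for TSV export."""
        return [(o, *self.orders[o]) for o in sorted(self.orders)]


def spectrum(
    model: "BooleanNetworkModel", include_constant_nodes: bool = False
) -> NonlinearitySpectrum:
    """Per-order nonlinearity spectrum of a network model.

    For each order ``l`` from 1 to the maximum in-degree, pools
    ``|d^alpha f_hat(1/2)|`` over every node with in-degree >= ``l`` and
    every alpha with ``|alpha| = l``, each normalized by
    :func:`max_abs_derivative` of that node's output bias.  Zero-valued
    terms still count: a node "contains" every multi-index its in-degree
    allows.

    Constant nodes (bias 0 or 1, including the self-input encoding of
    source nodes) have every derivative provably zero and a degenerate
    0/0 normalization; they are excluded by default, so a network of
    constants has an empty spectrum.  With ``include_constant_nodes`` their
    terms enter as exact zeros instead.

    Returns the pooled mean, population standard deviation and term count
    per order.
    """
    pooled: dict[int, list[np.ndarray]] = {}
    for node in model.nodes:
        table = model.tables[node]
        if table.bias in (0.0, 1.0) and not include_constant_nodes:
            continue
        d = decompose(table)
        bias = table.bias
        orders = d.orders
        for level in range(1, table.k + 1):
            vals = np.abs(d.coeffs[orders == level])
            bound = max_abs_derivative(bias, level)
            normalized = vals / bound if bound > 0 else np.zeros_like(vals)
            pooled.setdefault(level, []).append(normalized)
    summary = {}
    for level, chunks in pooled.items():
        allvals = np.concatenate(chunks)
        summary[level] = (
            float(allvals.mean()),
            float(allvals.std()),
            int(allvals.size),
        )
    return NonlinearitySpectrum(orders=summary)
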