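"""Synchronous Boolean / truncated-continuous simulation and approximability.

The exact dynamics update every node simultaneously by its Boolean rule.
The order-``m`` approximate dynamics replace each node's rule by the Taylor
truncation of its multilinear extension (centered at 1/2) to order
``min(m, in-degree)``, clamping every state to [0, 1] after each step.

Approximation quality is scored by the mean approximation error

    MAE(model, m) = mean over initial states and nodes of
                    (exact final state - approximate final state)^2,

taken at the last update step, with both simulators fed the same random
binary initial states.  A model's MAE is benchmarked against two null
ensembles (see :mod:`booltaylor.ensembles`):

    PMAE_X          = 100 * (MAE_X - MAE_unconstrained) / MAE_unconstrained
    approximability = PMAE_constrained - PMAE_model

so positive approximability means the model is easier to approximate at
that order than bias- and wiring-matched random logic.  "Linear
approximability" is the approximability at order 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ensembles import EnsembleSpec, constrained_ensemble, unconstrained_ensemble
from .network_io import BooleanNetworkModel
from .taylor import TaylorDecomposition, decompose

__all__ = [
    "SimulationConfig",
    "ApproximationReport",
    "random_initial_states",
    "simulate_exact",
    "simulate_truncated",
    "mae",
    "benchmark",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation and benchmarking knobs.

    Defaults mirror the benchmarking protocol for published models: 1000
    random initial states iterated 500 synchronous steps.  ``orders=None``
    means every order from 0 to the model's maximum in-degree.
    """

    n_init: int = 1000
    steps: int = 500
    seed: int = 0
    orders: tuple[int, ...] | None = None
    time_average: bool = False  # score the whole trajectory instead of the final step

    def __post_init__(self) -> None:
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.orders is not None:
            orders = tuple(int(o) for o in self.orders)
            if any(o < 0 for o in orders):
                raise ValueError("orders must be non-negative")
            object.__setattr__(self, "orders", orders)

    def resolve_orders(self, model: BooleanNetworkModel) -> tuple[int, ...]:
        if self.orders is not None:
            return self.orders
        return tuple(range(0, model.max_indegree() + 1))


class _CompiledModel:
    """Per-node regulator indices, output vectors and Taylor coefficients."""

    def __init__(self, model: BooleanNetworkModel):
        self.model = model
        index = {name: i for i, name in enumerate(model.nodes)}
        self.reg_idx = [
            np.array([index[r] for r in model.inputs[v]], dtype=np.int64)
            for v in model.nodes
        ]
        self.outputs = [model.tables[v].outputs for v in model.nodes]
        self.place = [
            (2 ** np.arange(len(idx) - 1, -1, -1)).astype(np.int64)
            for idx in self.reg_idx
        ]
        self.decompositions = [decompose(model.tables[v]) for v in model.nodes]

    def truncated(self, order: int) -> list[np.ndarray]:
        return [
            d.truncated_coeffs(min(order, d.k)) for d in self.decompositions
        ]


def random_initial_states(
    model: BooleanNetworkModel, n_init: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Uniform random binary initial states, shape ``(n_init, n_nodes)``.

    States are drawn independently; uniqueness is not enforced (``n_init``
    may exceed ``2^n`` for small networks).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.integers(0, 2, size=(n_init, model.n_nodes)).astype(np.uint8)


def simulate_exact(
    model: BooleanNetworkModel,
    initial_states: np.ndarray,
    steps: int,
    record_trajectory: bool = False,
    _compiled: "_CompiledModel | None" = None,
) -> np.ndarray:
    """Synchronous Boolean simulation.

    Returns the final states ``(n_init, n_nodes)`` or, with
    ``record_trajectory``, the whole trajectory
    ``(steps + 1, n_init, n_nodes)`` including the initial states.
    """
    comp = _compiled or _CompiledModel(model)
    states = np.asarray(initial_states, dtype=np.uint8)
    if states.ndim != 2 or states.shape[1] != model.n_nodes:
        raise ValueError(f"initial states must be (n, {model.n_nodes})")
    traj = [states] if record_trajectory else None
    for _ in range(steps):
        nxt = np.empty_like(states)
        for j in range(model.n_nodes):
            codes = states[:, comp.reg_idx[j]].astype(np.int64) @ comp.place[j]
            nxt[:, j] = comp.outputs[j][codes]
        states = nxt
        if traj is not None:
            traj.append(states)
    return np.stack(traj) if traj is not None else states


def simulate_truncated(
    model: BooleanNetworkModel,
    order: int,
    initial_states: np.ndarray,
    steps: int,
    record_trajectory: bool = False,
    decompositions: Sequence[TaylorDecomposition] | None = None,
    _compiled: "_CompiledModel | None" = None,
) -> np.ndarray:
    """Continuous simulation of the order-truncated network.

    Each node updates to the order-``min(order, k)`` truncation of its
    decomposition evaluated at the current regulator states; all states are
    reset to the nearest boundary of [0, 1] after every synchronous step.
    ``order >= max in-degree`` reproduces the exact Boolean dynamics from
    binary starts.
    """
    comp = _compiled or _CompiledModel(model)
    if decompositions is not None:
        comp.decompositions = list(decompositions)
    states = np.asarray(initial_states, dtype=np.float64)
    if states.ndim != 2 or states.shape[1] != model.n_nodes:
        raise ValueError(f"initial states must be (n, {model.n_nodes})")
    coeff_sets = comp.truncated(order)
    traj = [states] if record_trajectory else None
    n = states.shape[0]
    for _ in range(steps):
        nxt = np.empty_like(states)
        for j in range(model.n_nodes):
            diffs = states[:, comp.reg_idx[j]] - comp.decompositions[j].center
            c = np.broadcast_to(coeff_sets[j], (n, coeff_sets[j].shape[0]))
            for col in range(diffs.shape[1]):
                half = c.shape[1] // 2
                c = c[:, :half] + diffs[:, col : col + 1] * c[:, half:]
            nxt[:, j] = c[:, 0]
        np.clip(nxt, 0.0, 1.0, out=nxt)
        states = nxt
        if traj is not None:
            traj.append(states)
    return np.stack(traj) if traj is not None else states


def mae(
    model: BooleanNetworkModel,
    order: int,
    config: SimulationConfig,
    initial_states: np.ndarray | None = None,
    _compiled: "_CompiledModel | None" = None,
) -> float:
    """Mean approximation error of the order-truncated dynamics.

    Mean over initial states and nodes of the squared difference between
    the exact Boolean and the truncated continuous states at the final step
    (or averaged over all steps when ``config.time_average`` is set).  Both
    simulators share the same binary initial states.
    """
    comp = _compiled or _CompiledModel(model)
    if initial_states is None:
        initial_states = random_initial_states(model, config.n_init, config.seed)
    record = config.time_average
    exact = simulate_exact(
        model, initial_states, config.steps, record_trajectory=record, _compiled=comp
    )
    approx = simulate_truncated(
        model, order, initial_states, config.steps, record_trajectory=record,
        _compiled=comp,
    )
    if record:
        return float(((exact[1:].astype(np.float64) - approx[1:]) ** 2).mean())
    return float(((exact.astype(np.float64) - approx) ** 2).mean())


@dataclass(frozen=True)
class ApproximationReport:
    """Per-order MAE/PMAE/approximability of a model against its ensembles.

    ``per_order[m]`` maps ``mae_model``, ``mae_constrained``,
    ``mae_unconstrained``, ``pmae_model``, ``pmae_constrained`` and
    ``approximability`` for order ``m``; PMAE entries are ``None`` when the
    unconstrained MAE is zero at that order (percent change undefined).
    """

    model_name: str
    per_order: dict[int, dict[str, float | None]]
    n_init: int
    steps: int
    ensemble_size: int
    seed: int

    @property
    def orders(self) -> tuple[int, ...]:
        return tuple(sorted(self.per_order))

    @property
    def linear_approximability(self) -> float | None:
        """Approximability at order 1 (None if order 1 was not evaluated or
        its PMAE is undefined)."""
        row = self.per_order.get(1)
        if row is None:
            return None
        return row["approximability"]

    def to_rows(self) -> list[dict]:
        rows = []
        for order in self.orders:
            row = {"model": self.model_name, "order": order}
            row.update(self.per_order[order])
            rows.append(row)
        return rows


def _pmae(mae_x: float, mae_unconstrained: float) -> float | None:
    if mae_unconstrained == 0.0:
        return None
    return 100.0 * (mae_x - mae_unconstrained) / mae_unconstrained


def benchmark(
    model: BooleanNetworkModel,
    ensemble_specs: tuple[EnsembleSpec, EnsembleSpec] | None = None,
    config: SimulationConfig = SimulationConfig(),
    ensemble_size: int = 100,
) -> ApproximationReport:
    """Benchmark a model's per-order MAE against its two null ensembles.

    The model and every ensemble member are simulated from the *same*
    random binary initial states; the ensemble MAE at each order is the
    mean over members.  PMAEs are percent changes relative to the
    unconstrained ensemble MAE, and approximability is
    ``PMAE_constrained - PMAE_model``.

    ``ensemble_specs`` may supply explicit (constrained, unconstrained)
    specs; by default both use ``ensemble_size`` members seeded from
    ``config.seed``.
    """
    if ensemble_specs is None:
        ensemble_specs = (
            EnsembleSpec(kind="constrained", size=ensemble_size, seed=config.seed + 1),
            EnsembleSpec(kind="unconstrained", size=ensemble_size, seed=config.seed + 2),
        )
    c_spec, u_spec = ensemble_specs
    if c_spec.kind != "constrained" or u_spec.kind != "unconstrained":
        raise ValueError("ensemble_specs must be (constrained, unconstrained)")

    orders = config.resolve_orders(model)
    inits = random_initial_states(model, config.n_init, config.seed)
    name = str(model.metadata.get("name", "model"))

    logger.info("benchmark %s: simulating model at orders %s", name, orders)
    comp = _CompiledModel(model)
    mae_model = {
        m: mae(model, m, config, initial_states=inits, _compiled=comp) for m in orders
    }

    def ensemble_mae(members: list[BooleanNetworkModel], label: str) -> dict[int, float]:
        totals = {m: 0.0 for m in orders}
        for i, member in enumerate(members):
            mcomp = _CompiledModel(member)
            for m in orders:
                totals[m] += mae(member, m, config, initial_states=inits, _compiled=mcomp)
            logger.debug("benchmark %s: %s member %d done", name, label, i)
        return {m: totals[m] / len(members) for m in orders}

    logger.info("benchmark %s: %d constrained members", name, c_spec.size)
    mae_c = ensemble_mae(constrained_ensemble(model, c_spec), "constrained")
    logger.info("benchmark %s: %d unconstrained members", name, u_spec.size)
    mae_u = ensemble_mae(unconstrained_ensemble(model, u_spec), "unconstrained")

    per_order: dict[int, dict[str, float | None]] = {}
    for m in orders:
        pmae_model = _pmae(mae_model[m], mae_u[m])
        pmae_c = _pmae(mae_c[m], mae_u[m])
        if pmae_model is None:
            logger.warning(
                "benchmark %s: unconstrained MAE is 0 at order %d; PMAE undefined",
                name, m,
            )
        per_order[m] = {
            "mae_model": mae_model[m],
            "mae_constrained": mae_c[m],
            "mae_unconstrained": mae_u[m],
            "pmae_model": pmae_model,
            "pmae_constrained": pmae_c,
            "approximability": (
                pmae_c - pmae_model
                if pmae_c is not None and pmae_model is not None
                else None
            ),
        }
    return ApproximationReport(
        model_name=name,
        per_order=per_order,
        n_init=config.n_init,
        steps=config.steps,
        ensemble_size=c_spec.size,
        seed=config.seed,
    )
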