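"""Null ensembles for benchmarking the regulatory nonlinearity of a network.

Two randomization schemes:

* **constrained** — keeps the network's wiring and each node's output bias
  exactly, randomizing only the logic: every node's output column is
  replaced by a uniform random permutation of itself.  Differences from
  these nulls isolate the *arrangement* of a rule's ones, i.e. its
  nonlinearity structure.
* **unconstrained** — a baseline that keeps only the node count: per-node
  (in-degree, bias) pairs are bootstrap-resampled from the source model
  (jointly by default, preserving their empirical coupling), wiring is
  re-drawn uniformly, and tables are uniform random at the resampled bias.

Member ``i`` of an ensemble uses the seed stream ``(spec.seed, i)``, so any
member is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .boolfunc import TruthTable
from .network_io import BooleanNetworkModel, random_table_with_bias

__all__ = ["EnsembleSpec", "constrained_ensemble", "unconstrained_ensemble"]


@dataclass(frozen=True)
class EnsembleSpec:
    """Which null ensemble to draw, how many members, from which seed."""

    kind: Literal["constrained", "unconstrained"]
    size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("constrained", "unconstrained"):
            raise ValueError(f"unknown ensemble kind {self.kind!r}")
        if self.size < 1:
            raise ValueError("ensemble size must be >= 1")


def _member_rng(spec: EnsembleSpec, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(index,)))


def constrained_member(
    model: BooleanNetworkModel, rng: np.random.Generator, name: str = ""
) -> BooleanNetworkModel:
    """One rule-shuffled null: same wiring, each output column permuted."""
    tables = {}
    for node in model.nodes:
        t = model.tables[node]
        tables[node] = TruthTable(
            k=t.k,
            outputs=rng.permutation(t.outputs),
            input_names=t.input_names,
        )
    meta = dict(model.metadata)
    meta["name"] = name or f"{meta.get('name', 'model')}-constrained"
    meta["ensemble"] = "constrained"
    return BooleanNetworkModel(
        nodes=model.nodes, inputs=dict(model.inputs), tables=tables, metadata=meta
    )


def constrained_ensemble(
    model: BooleanNetworkModel, spec: EnsembleSpec
) -> list[BooleanNetworkModel]:
    """Ensemble of rule-shuffled nulls preserving wiring and per-node bias.

    Each member keeps the model's regulator lists exactly; each node's
    output column is an independent uniform permutation of the original, so
    ``|R1|`` — hence the output bias — is conserved member by member.
    """
    if spec.kind != "constrained":
        raise ValueError("spec.kind must be 'constrained'")
    return [
        constrained_member(
            model, _member_rng(spec, i), name=f"{model.metadata.get('name','model')}-c{i}"
        )
        for i in range(spec.size)
    ]


def unconstrained_member(
    model: BooleanNetworkModel,
    rng: np.random.Generator,
    joint: bool = True,
    name: str = "",
) -> BooleanNetworkModel:
    """One bootstrap-resampled null: new wiring, resampled (k, bias) pairs."""
    n = model.n_nodes
    ks = np.array([model.tables[v].k for v in model.nodes])
    bs = np.array([model.tables[v].bias for v in model.nodes])
    if joint:
        rows = rng.integers(0, n, size=n)
        new_ks, new_bs = ks[rows], bs[rows]
    else:
        new_ks = ks[rng.integers(0, n, size=n)]
        new_bs = bs[rng.integers(0, n, size=n)]
    inputs: dict[str, tuple[str, ...]] = {}
    tables: dict[str, TruthTable] = {}
    for j, node in enumerate(model.nodes):
        k = int(min(new_ks[j], n))
        regs = tuple(model.nodes[i] for i in rng.choice(n, size=k, replace=False))
        inputs[node] = regs
        tables[node] = random_table_with_bias(k, float(new_bs[j]), rng, input_names=regs)
    meta = dict(model.metadata)
    meta["name"] = name or f"{meta.get('name', 'model')}-unconstrained"
    meta["ensemble"] = "unconstrained"
    return BooleanNetworkModel(
        nodes=model.nodes, inputs=inputs, tables=tables, metadata=meta
    )


def unconstrained_ensemble(
    model: BooleanNetworkModel, spec: EnsembleSpec, joint: bool = True
) -> list[BooleanNetworkModel]:
    """Ensemble of baseline nulls with bootstrapped (in-degree, bias) pairs.

    With ``joint=True`` (default) each member node draws a whole
    ``(k, bias)`` pair with replacement from the source model's per-node
    pairs; ``joint=False`` resamples the two marginals independently.
    Wiring is re-drawn uniformly (distinct regulators, self-loops allowed)
    and tables are uniform random with ``round(bias * 2^k)`` ones.
    """
    if spec.kind != "unconstrained":
        raise ValueError("spec.kind must be 'unconstrained'")
    return [
        unconstrained_member(
            model,
            _member_rng(spec, i),
            joint=joint,
            name=f"{model.metadata.get('name','model')}-u{i}",
        )
        for i in range(spec.size)
    ]
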