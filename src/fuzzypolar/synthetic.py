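"""Random Boolean regulatory networks and exact Boolean oracles.

The generator emulates the structural class the analysis assumes: signed
Boolean networks with clamp-only extracellular inputs and internal nodes
each governed by an AND/OR/NOT rule over a bounded number of regulators.
Together with the exhaustive synchronous-attractor oracle it makes every
pipeline stage testable without the vendored macrophage fixture.

Synchronous update is used for the oracle. Fixed points do not depend on
the update scheme, and the oracle's role here is fixed-point and
Boolean-limit testing of the fuzzy transformation.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np

from .network import (
    And,
    BooleanRule,
    Expr,
    Node,
    NodeClass,
    Not,
    Or,
    RegulatoryNetwork,
    Var,
    boolean_evaluate,
)

__all__ = [
    "SyntheticSpec",
    "BooleanAttractors",
    "random_boolean_network",
    "boolean_attractors_synchronous",
    "make_initial_state",
    "embed_boolean_state",
    "PHENOTYPE_CORES",
]


@dataclass
class SyntheticSpec:
    """Parameters of the random-network generator.

    n_tf : number of internal (ruled) nodes, >= 1
    n_input : number of extracellular input nodes
    k : maximum regulators per rule, 1 <= k <= n_tf + n_input
    p_not : probability (in 1/100 units internally) a literal is negated
    seed : generator seed; identical specs yield identical networks
    """

    n_tf: int
    n_input: int = 0
    k: int = 2
    p_not: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tf < 1:
            raise ValueError("n_tf must be >= 1")
        if self.n_input < 0:
            raise ValueError("n_input must be >= 0")
        if not 1 <= self.k <= self.n_tf + self.n_input:
            raise ValueError("k must satisfy 1 <= k <= n_tf + n_input")
        if not 0.0 <= self.p_not <= 1.0:
            raise ValueError("p_not must lie in [0, 1]")


def random_boolean_network(spec: SyntheticSpec) -> RegulatoryNetwork:
    """Generate a random network: one AND/OR tree per internal node.

    Each internal node receives k' <= k distinct regulators folded
    left-associatively with random AND/OR connectives; each literal is
    negated with probability ``p_not``. The generation path uses only
    integer draws, so identical seeds reproduce identical networks on any
    platform.
    """
    rng = random.Random(spec.seed)
    tf_names = [f"G{i}" for i in range(spec.n_tf)]
    input_names = [f"X{i}" for i in range(spec.n_input)]
    all_names = input_names + tf_names
    p_not_pct = int(round(spec.p_not * 100))

    nodes = [Node(n, NodeClass.extracellular) for n in input_names] + [
        Node(n, NodeClass.transcription_factor) for n in tf_names
    ]
    rules: dict[str, BooleanRule] = {}
    for target in tf_names:
        k_eff = 1 + rng.randrange(spec.k)
        regulators = rng.sample(all_names, k_eff)

        def literal(name: str) -> Expr:
            leaf: Expr = Var(name)
            return Not(leaf) if rng.randrange(100) < p_not_pct else leaf

        expr = literal(regulators[0])
        for reg in regulators[1:]:
            op = And if rng.randrange(2) == 0 else Or
            expr = op(expr, literal(reg))
        rules[target] = BooleanRule(target, expr)
    return RegulatoryNetwork(nodes=nodes, rules=rules)


@dataclass
class BooleanAttractors:
    """Synchronous attractors of a network under a fixed input assignment.

    ``fixed_points`` and ``cycles`` list attractor states as 0/1 tuples over
    ``tf_names`` (input values are in ``input_assignment``); ``basin_sizes``
    aligns with ``fixed_points + cycles`` and sums to 2**len(tf_names).
    """

    tf_names: list[str]
    input_assignment: dict[str, int]
    fixed_points: list[tuple[int, ...]]
    cycles: list[list[tuple[int, ...]]]
    basin_sizes: list[int]

    @property
    def n_states(self) -> int:
        return 2 ** len(self.tf_names)


def boolean_attractors_synchronous(
    network: RegulatoryNetwork,
    input_assignment: Mapping[str, int] | None = None,
) -> BooleanAttractors:
    """Exhaustive synchronous state-space analysis (TF count <= 20).

    Partitions all 2**n internal states into attractor basins under the
    synchronous update, returning fixed points, cycles and basin sizes.
    """
    tf_names = network.tf_nodes
    n = len(tf_names)
    if n > 20:
        raise ValueError(f"state space 2**{n} too large for exhaustive search")
    inputs = {name: 0 for name in network.input_nodes}
    if input_assignment:
        for name, value in input_assignment.items():
            if name not in inputs:
                raise KeyError(f"{name!r} is not an input node")
            inputs[name] = int(value)

    rules = [network.rules[t] for t in tf_names]

    def successor(code: int) -> int:
        state = dict(inputs)
        for i, name in enumerate(tf_names):
            state[name] = (code >> i) & 1
        nxt = 0
        for i, rule in enumerate(rules):
            nxt |= boolean_evaluate(rule, state) << i
        return nxt

    n_states = 1 << n
    succ = [successor(s) for s in range(n_states)]

    attractor_of = [-1] * n_states  # attractor id per state
    attractors: list[list[int]] = []  # each a list of state codes (cycle order)
    for start in range(n_states):
        if attractor_of[start] >= 0:
            continue
        path: list[int] = []
        pos: dict[int, int] = {}
        s = start
        while attractor_of[s] < 0 and s not in pos:
            pos[s] = len(path)
            path.append(s)
            s = succ[s]
        if attractor_of[s] >= 0:
            aid = attractor_of[s]
        else:
            aid = len(attractors)
            attractors.append(path[pos[s]:])
        for state in path:
            attractor_of[state] = aid

    basin_count = [0] * len(attractors)
    for aid in attractor_of:
        basin_count[aid] += 1

    def decode(code: int) -> tuple[int, ...]:
        return tuple((code >> i) & 1 for i in range(n))

    fixed_points: list[tuple[int, ...]] = []
    cycles: list[list[tuple[int, ...]]] = []
    fp_basins: list[int] = []
    cyc_basins: list[int] = []
    for aid, cycle in enumerate(attractors):
        if len(cycle) == 1:
            fixed_points.append(decode(cycle[0]))
            fp_basins.append(basin_count[aid])
        else:
            cycles.append([decode(c) for c in cycle])
            cyc_basins.append(basin_count[aid])
    return BooleanAttractors(
        tf_names=tf_names,
        input_assignment=inputs,
        fixed_points=fixed_points,
        cycles=cycles,
        basin_sizes=fp_basins + cyc_basins,
    )


def embed_boolean_state(
    network: RegulatoryNetwork,
    tf_state: Sequence[int],
    input_assignment: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Embed a 0/1 internal state as a real state vector over all nodes."""
    tf_names = network.tf_nodes
    if len(tf_state) != len(tf_names):
        raise ValueError("tf_state length does not match TF node count")
    q = np.zeros(len(network))
    idx = network.index
    for name, value in zip(tf_names, tf_state):
        q[idx[name]] = float(value)
    if input_assignment:
        for name, value in input_assignment.items():
            q[idx[name]] = float(value)
    return q


# Reconstructed 0/1 core states for the macrophage fixture: each phenotype's
# marker transcription factor(s) plus its canonical secretory partners under
# the vendored rules. Synthetic stand-ins for the published attractor table
# (which is supplementary material not vendored here); only the M1 core is a
# self-sustaining Boolean fixed point of the reconstruction at zero inputs.
PHENOTYPE_CORES: dict[str, frozenset[str]] = {
    "M0": frozenset(),
    "M1": frozenset({"NFkB", "TNFA", "IL12", "IL6"}),
    "M1a": frozenset({"STAT1", "IL12"}),
    "M2a": frozenset({"STAT6", "SOCS1"}),
    "M2b": frozenset({"ERK", "AP1", "IL6"}),
    "M2c": frozenset({"STAT3", "SOCS3", "IL10"}),
    "M2d": frozenset({"HIF1a", "VEGF"}),
}

_TAG_RE = re.compile(r"M1a|M2a|M2b|M2c|M2d|M1|M0")


def make_initial_state(
    network: RegulatoryNetwork,
    phenotype: Union[str, Sequence[float], Mapping[str, float]],
) -> np.ndarray:
    """Initial state vector from a phenotype name, vector, or mapping.

    Names are canonical phenotype labels ("M0", "M1", hybrids like "M1M2b"
    as unions of the pure cores); vectors must match the node count;
    mappings set the named nodes on an all-zero background. Unknown
    phenotype names raise ``ValueError``.
    """
    if isinstance(phenotype, str):
        matches = _TAG_RE.findall(phenotype)
        if not matches or "".join(matches) != phenotype:
            raise ValueError(f"unknown phenotype name {phenotype!r}")
        active: set[str] = set()
        for tag in matches:
            active |= PHENOTYPE_CORES[tag]
        missing = [n for n in active if n not in network.index]
        if missing:
            raise ValueError(
                f"phenotype {phenotype!r} references nodes absent from the "
                f"network: {sorted(missing)}"
            )
        return make_initial_state(network, {n: 1.0 for n in active})
    if isinstance(phenotype, Mapping):
        q = np.zeros(len(network))
        idx = network.index
        for name, value in phenotype.items():
            q[idx[name]] = float(value)
        return q
    q = np.asarray(phenotype, dtype=float)
    if q.shape != (len(network),):
        raise ValueError(
            f"state vector has shape {q.shape}, expected ({len(network)},)"
        )
    return q.copy()
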