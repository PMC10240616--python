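"""Fuzzy-logic transformation of Boolean rules and ODE assembly.

The probabilistic fuzzy operators replace the Boolean connectives by

    q AND p -> q*p        q OR p -> q + p - q*p        NOT p -> 1 - p

so each rule's truth value ``omega_i`` becomes a polynomial on the unit box
that coincides with the Boolean value on {0,1} inputs. The activation drive
of a node is the sigmoid characteristic

    phi[omega] = 1 / (1 + exp(-b (omega - omega_thr)))

with steepness ``b`` and threshold ``omega_thr`` (0.5 by default: a rule
that is "half true" drives the node to half-maximal expression). The
continuous dynamics for every node i carrying a rule are

    dq_i/dt = phi[omega_i(q)] - alpha_i q_i

with unit decay rates by default, so the stationary expression of a node
equals the degree of truth of its fuzzy proposition passed through phi.
Extracellular nodes carry no rule: they are state components with zero
derivative, held at whatever value they are clamped to, which keeps the
state dimension equal to the full node count (29 for the macrophage
network).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence, Union

import numpy as np

from .network import (
    And,
    BooleanRule,
    Const,
    Expr,
    Node,
    NodeClass,
    Not,
    Or,
    RegulatoryNetwork,
    Var,
)

__all__ = [
    "FuzzyParameters",
    "FuzzyODESystem",
    "fuzzify_expression",
    "characteristic",
    "build_ode_system",
    "equations_text",
]

#: Default sigmoid steepness. Large enough that the Boolean-limit residual
#: exp(-b/2) ~ 3e-7 is negligible and that a directly driven node crosses the
#: 0.25/0.75 labeling thresholds within +-ln(3)/b ~ 0.037 of the half-maximal
#: input, matching the reported width of dose-response uncertainty bands.
DEFAULT_B = 30.0


@dataclass
class FuzzyParameters:
    """Parameters of the fuzzy transformation.

    b : sigmoid steepness (dimensionless, > 0)
    omega_thr : activation threshold in (0, 1); 0.5 by default
    alpha : per-node decay rate (1/time); scalar or vector, 1 everywhere
        by default so the stationary state is phi[omega] itself
    """

    b: float = DEFAULT_B
    omega_thr: float = 0.5
    alpha: Union[float, np.ndarray] = 1.0

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ValueError("steepness b must be > 0")
        if not 0 < self.omega_thr < 1:
            raise ValueError("omega_thr must lie strictly inside (0, 1)")
        alpha = np.asarray(self.alpha, dtype=float)
        if np.any(alpha <= 0):
            raise ValueError("all decay rates alpha must be > 0")


def characteristic(
    omega: Union[float, np.ndarray], params: FuzzyParameters
) -> Union[float, np.ndarray]:
    """Sigmoid activation level phi[omega] in (0, 1).

    Strictly increasing in omega; equals 0.5 at omega = omega_thr for every
    steepness b; satisfies the symmetry phi(w) + phi(2*omega_thr - w) = 1.
    """
    omega = np.asarray(omega, dtype=float)
    out = 1.0 / (1.0 + np.exp(-params.b * (omega - params.omega_thr)))
    return float(out) if out.ndim == 0 else out


def fuzzify_expression(
    rule: Union[BooleanRule, Expr],
    index: dict[str, int] | None = None,
) -> Callable:
    """Compile a Boolean rule into its probabilistic fuzzy evaluator.

    With ``index`` given, returns ``f(q)`` over a state vector; otherwise
    returns ``f(state_dict)`` over a name->value mapping. The evaluator is
    the structural recursion AND -> product, OR -> probabilistic sum,
    NOT -> complement, so it maps the unit box into [0, 1] and agrees with
    ``boolean_evaluate`` on 0/1 inputs.
    """
    expr = rule.expression if isinstance(rule, BooleanRule) else rule
    if index is None:
        return _compile_dict(expr)
    return _compile_vec(expr, index)


def _compile_vec(expr: Expr, index: dict[str, int]) -> Callable:
    if isinstance(expr, Var):
        i = index[expr.name]
        return lambda q: q[i]
    if isinstance(expr, Const):
        v = float(expr.value)
        return lambda q: v
    if isinstance(expr, Not):
        f = _compile_vec(expr.operand, index)
        return lambda q: 1.0 - f(q)
    if isinstance(expr, And):
        fl, fr = _compile_vec(expr.left, index), _compile_vec(expr.right, index)
        return lambda q: fl(q) * fr(q)
    if isinstance(expr, Or):
        fl, fr = _compile_vec(expr.left, index), _compile_vec(expr.right, index)

        def _or(q, fl=fl, fr=fr):
            a, b = fl(q), fr(q)
            return a + b - a * b

        return _or
    raise TypeError(f"unknown expression node {expr!r}")


def _compile_dict(expr: Expr) -> Callable:
    names = sorted(expr.names())
    index = {n: i for i, n in enumerate(names)}
    f = _compile_vec(expr, index)

    def evaluator(state):
        q = np.array([state[n] for n in names], dtype=float)
        return float(f(q))

    return evaluator


@dataclass
class FuzzyODESystem:
    """The assembled continuous system for one network.

    ``omega(q)`` returns the vector of fuzzy-proposition values (NaN for
    input nodes, which have no rule); ``rhs(t, q)`` is the ODE right-hand
    side with zero derivative on input and clamped components.
    """

    network: RegulatoryNetwork
    params: FuzzyParameters
    clamped: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.network.index
        self._names = self.network.names
        self._n = len(self._names)
        self._rule_idx: list[int] = []
        self._rule_fns: list[Callable] = []
        for name in self._names:
            rule = self.network.rules.get(name)
            if rule is not None:
                self._rule_idx.append(idx[name])
                self._rule_fns.append(fuzzify_expression(rule, idx))
        self._rule_idx_arr = np.array(self._rule_idx, dtype=int)
        alpha = np.asarray(self.params.alpha, dtype=float)
        if alpha.ndim == 0:
            alpha = np.full(self._n, float(alpha))
        elif alpha.shape != (self._n,):
            raise ValueError(
                f"alpha vector length {alpha.shape} does not match {self._n} nodes"
            )
        self._alpha = alpha
        for name in self.clamped:
            if name not in idx:
                raise KeyError(f"clamped node {name!r} not in network")
        self._clamp_idx = np.array(
            [idx[n] for n in self.clamped], dtype=int
        )
        self._clamp_val = np.array(
            [float(v) for v in self.clamped.values()], dtype=float
        )

    @property
    def dimension(self) -> int:
        """State dimension: one component per node, inputs included."""
        return self._n

    @property
    def names(self) -> list[str]:
        return self._names

    def omega(self, q: np.ndarray) -> np.ndarray:
        """Fuzzy truth values omega_i(q); NaN for nodes without a rule."""
        q = np.asarray(q, dtype=float)
        out = np.full(self._n, np.nan)
        for i, fn in zip(self._rule_idx, self._rule_fns):
            out[i] = fn(q)
        return out

    def phi(self, q: np.ndarray) -> np.ndarray:
        """phi[omega_i(q)]; NaN for nodes without a rule."""
        return characteristic(self.omega(q), self.params)

    def rhs(self, t: float, q: np.ndarray) -> np.ndarray:
        """dq/dt: phi[omega]-alpha*q on ruled nodes, 0 on inputs and clamps."""
        q = np.asarray(q, dtype=float)
        dq = np.zeros(self._n)
        for i, fn in zip(self._rule_idx, self._rule_fns):
            drive = 1.0 / (
                1.0 + np.exp(-self.params.b * (fn(q) - self.params.omega_thr))
            )
            dq[i] = drive - self._alpha[i] * q[i]
        if len(self._clamp_idx):
            dq[self._clamp_idx] = 0.0
        return dq

    def enforce_clamps(self, q: np.ndarray) -> np.ndarray:
        """Return a copy of q with clamped components set bit-exactly."""
        q = np.array(q, dtype=float)
        if len(self._clamp_idx):
            q[self._clamp_idx] = self._clamp_val
        return q

    def with_clamps(self, clamps: dict[str, float]) -> "FuzzyODESystem":
        merged = dict(self.clamped)
        merged.update(clamps)
        return FuzzyODESystem(self.network, self.params, merged)


def build_ode_system(
    network: RegulatoryNetwork, params: FuzzyParameters | None = None
) -> FuzzyODESystem:
    """Assemble dq_i/dt = phi[omega_i(q)] - alpha_i q_i for a network.

    Input (extracellular) nodes become zero-derivative state components, so
    the state dimension equals the node count.
    """
    return FuzzyODESystem(network, params or FuzzyParameters())


def equations_text(system: FuzzyODESystem) -> str:
    """Human-readable equations, one line per node, for audit.

    Input nodes are listed as held constant; clamp assignments are recorded.
    """
    lines = [
        f"# b={system.params.b}, omega_thr={system.params.omega_thr}",
    ]
    for name in system.names:
        rule = system.network.rules.get(name)
        if name in system.clamped:
            lines.append(f"{name} = {system.clamped[name]}  (clamped)")
        elif rule is None:
            lines.append(f"d{name}/dt = 0  (extracellular input)")
        else:
            lines.append(f"d{name}/dt = phi[{rule.expression}] - {name}")
    return "\n".join(lines) + "\n"
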