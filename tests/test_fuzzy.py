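"""Fuzzy transformation: probabilistic operators, sigmoid, ODE assembly."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fuzzypolar as fp
from fuzzypolar.fuzzy import DEFAULT_B
from fuzzypolar.network import And, Const, Expr, Not, Or, Var, boolean_evaluate
from fuzzypolar.synthetic import (
    SyntheticSpec,
    boolean_attractors_synchronous,
    embed_boolean_state,
    random_boolean_network,
)

PARAMS_B10 = fp.FuzzyParameters(b=10.0)


# --- expression strategy over a small variable pool ------------------------

_names = st.sampled_from(["p", "q", "r"])


def exprs(max_depth=4):
    leaves = st.one_of(_names.map(Var), st.sampled_from([Const(0), Const(1)]))
    return st.recursive(
        leaves,
        lambda children: st.one_of(
            children.map(Not),
            st.tuples(children, children).map(lambda lr: And(*lr)),
            st.tuples(children, children).map(lambda lr: Or(*lr)),
        ),
        max_leaves=8,
    )


class TestFuzzifyExpression:
    @pytest.mark.parametrize(
        "text, state, expected",
        [
            ("q AND p", {"q": 0.5, "p": 0.5}, 0.25),
            ("q OR p", {"q": 0.5, "p": 0.5}, 0.75),
            ("NOT p", {"p": 0.3}, 0.7),
            ("q AND NOT p", {"q": 0.8, "p": 0.25}, 0.6),
        ],
    )
    def test_probabilistic_rules(self, text, state, expected):
        f = fp.fuzzify_expression(fp.parse_rule(text))
        assert f(state) == pytest.approx(expected, abs=1e-15)

    def test_operator_grid(self):
        """AND -> q*p, OR -> q+p-q*p on a grid covering the unit square."""
        f_and = fp.fuzzify_expression(fp.parse_rule("q AND p"))
        f_or = fp.fuzzify_expression(fp.parse_rule("q OR p"))
        f_not = fp.fuzzify_expression(fp.parse_rule("NOT p"))
        for q in np.linspace(0, 1, 11):
            for p in np.linspace(0, 1, 11):
                state = {"q": q, "p": p}
                assert f_and(state) == pytest.approx(q * p, abs=1e-12)
                assert f_or(state) == pytest.approx(q + p - q * p, abs=1e-12)
            assert f_not({"p": q}) == pytest.approx(1 - q, abs=1e-12)

    @given(exprs(), st.lists(st.floats(0, 1), min_size=3, max_size=3))
    def test_closure_unit_interval(self, expr, values):
        """Structural induction: fuzzy value stays inside [0, 1]."""
        state = dict(zip("pqr", values))
        value = fp.fuzzify_expression(expr)(state) if expr.names() else None
        if value is None:
            value = fp.fuzzify_expression(expr)({"p": 0, "q": 0, "r": 0})
        assert -1e-12 <= value <= 1 + 1e-12

    @given(exprs())
    def test_boolean_consistency_on_corners(self, expr):
        """On 0/1 states the fuzzy value equals the Boolean truth value."""
        f = fp.fuzzify_expression(expr)
        for bits in itertools.product((0, 1), repeat=3):
            state = dict(zip("pqr", bits))
            assert f(state) == boolean_evaluate(expr, state)

    def test_fold_order_immaterial(self):
        """Fuzzy AND/OR are associative and commutative, so n-ary folds agree."""
        state = {"p": 0.3, "q": 0.6, "r": 0.9}
        for op in ("AND", "OR"):
            left = fp.fuzzify_expression(fp.parse_rule(f"(p {op} q) {op} r"))(state)
            right = fp.fuzzify_expression(fp.parse_rule(f"p {op} (q {op} r)"))(state)
            swapped = fp.fuzzify_expression(fp.parse_rule(f"r {op} (q {op} p)"))(state)
            assert left == pytest.approx(right, abs=1e-15)
            assert left == pytest.approx(swapped, abs=1e-15)


class TestCharacteristic:
    @pytest.mark.parametrize("b", [1.0, 10.0, 100.0])
    def test_midpoint_is_half(self, b):
        params = fp.FuzzyParameters(b=b)
        assert fp.characteristic(0.5, params) == pytest.approx(0.5, abs=1e-15)

    def test_closed_form_values(self):
        assert fp.characteristic(1.0, PARAMS_B10) == pytest.approx(
            1 / (1 + np.exp(-5)), abs=1e-12
        )
        assert fp.characteristic(0.0, PARAMS_B10) == pytest.approx(
            1 / (1 + np.exp(5)), abs=1e-12
        )

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_monotone_and_symmetric(self, w1, w2):
        lo, hi = sorted((w1, w2))
        assert fp.characteristic(lo, PARAMS_B10) <= fp.characteristic(hi, PARAMS_B10)
        # phi(w) + phi(2*thr - w) = 1
        total = fp.characteristic(w1, PARAMS_B10) + fp.characteristic(
            1.0 - w1, PARAMS_B10
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_steepness_ordering(self):
        # above threshold, larger b means stronger activation
        weak = fp.characteristic(0.7, fp.FuzzyParameters(b=5))
        strong = fp.characteristic(0.7, fp.FuzzyParameters(b=50))
        assert weak < strong

    @pytest.mark.parametrize(
        "kwargs", [{"b": 0.0}, {"b": -1.0}, {"omega_thr": 0.0}, {"omega_thr": 1.5}]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            fp.FuzzyParameters(**kwargs)


class TestBuildODESystem:
    def test_macrophage_dimension_is_29(self, mac_system):
        assert mac_system.dimension == 29

    def test_relay_rhs_value(self, relay_net):
        system = fp.build_ode_system(relay_net, PARAMS_B10)
        q = np.array([1.0, 0.0])  # A=1, B=0
        dq = system.rhs(0.0, q)
        assert dq[0] == 0.0  # input: zero derivative
        assert dq[1] == pytest.approx(1 / (1 + np.exp(-5)), abs=1e-12)

    def test_fixed_point_condition(self, relay_net):
        system = fp.build_ode_system(relay_net, PARAMS_B10)
        qb = 1 / (1 + np.exp(-5))
        dq = system.rhs(0.0, np.array([1.0, qb]))
        assert abs(dq[1]) < 1e-12

    def test_omega_nan_for_inputs(self, mac_system):
        omega = mac_system.omega(np.zeros(29))
        idx = mac_system.network.index
        assert np.isnan(omega[idx["IFNG"]])
        assert not np.isnan(omega[idx["STAT1"]])

    def test_forward_invariance_bounds_at_faces(self, mac_system):
        """phi in (0,1) with alpha=1 pushes the flow into the unit box."""
        rng = np.random.default_rng(7)
        idx = [mac_system.names.index(n) for n in mac_system.network.tf_nodes]
        for _ in range(20):
            q = rng.uniform(0, 1, 29)
            q[idx[0]] = 0.0
            dq = mac_system.rhs(0.0, q)
            assert dq[idx[0]] > 0.0
            q[idx[0]] = 1.0
            dq = mac_system.rhs(0.0, q)
            assert dq[idx[0]] < 0.0

    def test_equations_text_audit_export(self, mac_system):
        text = fp.equations_text(mac_system)
        lines = [l for l in text.splitlines() if not l.startswith("#")]
        assert len(lines) == 29
        assert any(l.startswith("dSTAT1/dt = phi[") for l in lines)
        assert sum("extracellular input" in l for l in lines) == 15


class TestBooleanLimit:
    @pytest.mark.parametrize("b", [10.0, 20.0, 50.0])
    def test_fixture_boolean_fixed_points_are_near_equilibria(self, mac_net, b):
        """At any synchronous Boolean fixed point the fuzzy RHS residual is
        bounded by exp(-b/2) (omega at a Boolean state is exactly 0 or 1)."""
        system = fp.build_ode_system(mac_net, fp.FuzzyParameters(b=b))
        att = boolean_attractors_synchronous(mac_net)
        assert att.fixed_points  # the monocyte state at least
        for fixed_point in att.fixed_points:
            q = embed_boolean_state(mac_net, fixed_point)
            residual = np.max(np.abs(system.rhs(0.0, q)))
            assert residual <= np.exp(-b / 2) + 1e-12

    def test_fuzzy_equals_boolean_on_all_rule_corners(self, mac_net):
        """Bitwise agreement over all 2^k literal combinations per rule."""
        for rule in mac_net.rules.values():
            names = sorted(rule.expression.names())
            f = fp.fuzzify_expression(rule)
            for bits in itertools.product((0, 1), repeat=len(names)):
                state = dict(zip(names, bits))
                assert f(state) == boolean_evaluate(rule, state)
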