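"""Decision-tree engine: rollback, ICER, dominance, rate conversion."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oacea import (
    ConfigError,
    Dominance,
    Expr,
    PayoffPair,
    TreeNode,
    TreeValidationError,
    UnboundParameterError,
    UndefinedICERError,
    classify_dominance,
    commercial_rate,
    compute_icer,
    incremental,
    rollback,
    truncate_dollars,
)
from oacea.synthetic import gen_tree


# ---------------------------------------------------------------------------
# Expressions
# ---------------------------------------------------------------------------

class TestExpr:
    def test_arithmetic_and_complement(self):
        e = Expr("1 - p")
        assert e({"p": 0.25}) == 0.75
        assert Expr("a + 2*b - c")({"a": 1.0, "b": 3.0, "c": 0.5}) == 6.5

    def test_unbound_parameter_named_in_error(self):
        with pytest.raises(UnboundParameterError) as exc:
            Expr("price + tax")({"price": 1.0})
        assert exc.value.parameter == "tax"

    @pytest.mark.parametrize("bad", ["p / q", "f(x)", "p ** 2", "__import__('os')",
                                     "[1, 2]", "'a'"])
    def test_disallowed_constructs_rejected(self, bad):
        with pytest.raises(ConfigError):
            Expr(bad)

    def test_elementwise_over_arrays(self):
        e = Expr("c + 2*x")
        out = e({"c": 1.0, "x": np.array([0.0, 1.0, 2.0])})
        assert np.array_equal(out, [1.0, 3.0, 5.0])


# ---------------------------------------------------------------------------
# Rollback
# ---------------------------------------------------------------------------

class TestRollback:
    def test_terminal_identity(self):
        leaf = TreeNode.terminal("t", 4635, 0.40)
        pair = rollback(leaf, {})
        assert (pair.cost, pair.effect) == (4635.0, 0.40)

    def test_chance_node_is_probability_weighted_mean(self):
        node = TreeNode.chance("c", [
            (0.5, TreeNode.terminal("a", 100, 0.2)),
            (0.5, TreeNode.terminal("b", 300, 0.4)),
        ])
        pair = rollback(node, {})
        assert pair.cost == pytest.approx(200.0)
        assert pair.effect == pytest.approx(0.3)

    def test_decision_node_reports_both_strategies(self):
        root = TreeNode.decision("root", [
            TreeNode.terminal("new", 10, 0.5),
            TreeNode.terminal("std", 5, 0.4),
        ])
        pairs = rollback(root, {})
        assert set(pairs) == {"new", "std"}
        assert pairs["new"].cost == 10.0

    def test_probabilities_must_sum_to_one(self):
        node = TreeNode.chance("broken", [
            (0.5, TreeNode.terminal("a", 1, 0)),
            (0.4, TreeNode.terminal("b", 2, 0)),
        ])
        with pytest.raises(TreeValidationError, match="broken"):
            rollback(node, {})

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_path_enumeration_oracle(self, seed):
        """Rollback equals brute-force path enumeration on random trees
        of depth <= 4 and branching <= 3."""
        rng = np.random.default_rng(seed)
        depth = int(rng.integers(1, 5))
        branching = int(rng.integers(2, 4))
        gen = gen_tree(depth, branching, seed=seed)
        env = {name: p.base for name, p in gen.parameters.items()}
        pair = rollback(gen.root, env)
        assert pair.cost == pytest.approx(gen.oracle.cost, rel=1e-9)
        assert pair.effect == pytest.approx(gen.oracle.effect, rel=1e-9)

    @pytest.mark.parametrize("k", [0.0, 0.5, 3.0])
    def test_linear_in_terminal_payoffs(self, k):
        """Scaling all terminal costs by k scales the rolled-back cost by k."""
        gen = gen_tree(3, 3, seed=11)
        env = {name: p.base for name, p in gen.parameters.items()}
        scaled = {
            name: (v * k if name.startswith("c_") else v) for name, v in env.items()
        }
        base = rollback(gen.root, env)
        out = rollback(gen.root, scaled)
        assert out.cost == pytest.approx(k * base.cost, abs=1e-9)
        assert out.effect == pytest.approx(base.effect)


# ---------------------------------------------------------------------------
# ICER
# ---------------------------------------------------------------------------

class TestICER:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((8641, 6282, 0.52, 0.39), 18146),
            ((13967, 9294, 0.77, 0.47), 15576),
            ((5000, 5000, 0.6, 0.4), 0),
        ],
    )
    def test_published_and_degenerate_examples(self, args, expected):
        assert truncate_dollars(compute_icer(*args)) == expected

    def test_undefined_on_equal_effect(self):
        with pytest.raises(UndefinedICERError):
            compute_icer(100, 50, 0.4, 0.4)

    @given(
        c1=st.floats(0, 1e5), c2=st.floats(0, 1e5),
        e1=st.floats(0, 1, exclude_min=True), e2=st.floats(0, 1),
    )
    def test_perspective_reversal_before_truncation(self, c1, c2, e1, e2):
        """Reversing the comparison perspective (swap both costs and
        effects) leaves the ratio unchanged; negating the incremental
        cost alone negates it."""
        if e1 == e2:
            return
        forward = compute_icer(c1, c2, e1, e2)
        assert compute_icer(c2, c1, e2, e1) == pytest.approx(
            forward, rel=1e-12, abs=1e-12
        )
        assert compute_icer(c2, c1, e1, e2) == pytest.approx(
            -forward, rel=1e-12, abs=1e-12
        )

    def test_truncation_is_toward_zero(self):
        assert truncate_dollars(18146.15) == 18146
        assert truncate_dollars(15576.67) == 15576
        assert truncate_dollars(-15576.67) == -15576


# ---------------------------------------------------------------------------
# Dominance classification
# ---------------------------------------------------------------------------

class TestDominance:
    @pytest.mark.parametrize(
        "dc,de,expected",
        [
            (2359.0, 0.13, Dominance.NE),
            (-1.0, 0.1, Dominance.DOMINANT),
            (1.0, -0.1, Dominance.DOMINATED),
            (-1.0, -0.1, Dominance.SW),
            (0.0, 0.0, Dominance.EQUAL),
            (0.0, 0.1, Dominance.EQUAL_COST),
            (0.0, -0.1, Dominance.EQUAL_COST),
            (5.0, 0.0, Dominance.EQUAL_EFFECT),
            (-5.0, 0.0, Dominance.EQUAL_EFFECT),
        ],
    )
    def test_sign_patterns(self, dc, de, expected):
        assert classify_dominance(dc, de) is expected

    @given(dc=st.floats(allow_nan=False, allow_infinity=False),
           de=st.floats(allow_nan=False, allow_infinity=False))
    def test_exhaustive_over_all_sign_patterns(self, dc, de):
        assert classify_dominance(dc, de) in Dominance

    def test_incremental_suppresses_icer_on_equal_effect(self):
        res = incremental(PayoffPair(100.0, 0.4), PayoffPair(50.0, 0.4))
        assert res.icer is None and res.icer_truncated is None
        assert res.classification is Dominance.EQUAL_EFFECT


# ---------------------------------------------------------------------------
# Medicare -> commercial rate conversion
# ---------------------------------------------------------------------------

class TestCommercialRate:
    def test_inverse_of_75_percent(self):
        assert commercial_rate(75.0) == pytest.approx(100.0)
        assert commercial_rate(0.0) == 0.0

    def test_dollar_becomes_1_33_rounded_to_cents(self):
        assert round(commercial_rate(1.00), 2) == 1.33

    def test_negative_rejected(self):
        with pytest.raises(ConfigError):
            commercial_rate(-1.0)
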