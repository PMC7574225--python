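"""Decision-tree engine for two-strategy cost-effectiveness models.

A model is a decision node whose children are the strategies under
comparison (e.g. a new therapy pathway versus standard of care). Below
each strategy, chance nodes carry branch probabilities and terminal
nodes carry a payoff pair: cumulative cost in USD and a dimensionless
effectiveness (an effect size on pain/function) accumulated over the
analytic horizon. Rollback evaluates the tree to the probability-weighted
expected payoff of each strategy; the incremental cost-effectiveness
ratio (ICER) and a dominance/quadrant classification summarise a pair of
strategies.

Branch probabilities and terminal payoffs are arithmetic expressions
over named parameters, restricted to ``+``, ``-``, ``*``, numeric
constants and parameter references — enough to express linear cost
accumulation (device price + per-session price x session count) and
probability complements ``1 - p``. Expressions evaluate elementwise when
parameter values are numpy arrays, which is how the probabilistic
sensitivity analysis vectorises over Monte-Carlo draws.
"""

from __future__ import annotations

import ast
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Mapping, Optional, Sequence, Union

import numpy as np

__all__ = [
    "PROB_SUM_TOL",
    "ModelError",
    "ConfigError",
    "UnboundParameterError",
    "TreeValidationError",
    "UndefinedICERError",
    "CalibrationError",
    "NoThresholdError",
    "Expr",
    "Role",
    "Parameter",
    "PayoffPair",
    "NodeKind",
    "Branch",
    "TreeNode",
    "Dominance",
    "IncrementalResult",
    "rollback",
    "compute_icer",
    "truncate_dollars",
    "classify_dominance",
    "incremental",
    "commercial_rate",
]

#: Absolute tolerance for the sum of branch probabilities at a chance node.
#: Complement-style expressions (p, 1 - p) sum exactly up to floating error.
PROB_SUM_TOL = 1e-9

#: Medicare payments are assumed to be this fraction of commercial payer
#: rates; the commercial conversion divides by it (exact ratio, the popular
#: "$1.33 per $1" multiplier is this ratio rounded to cents).
MEDICARE_TO_COMMERCIAL_FRACTION = 0.75


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class ModelError(Exception):
    """Base class for model construction and evaluation errors."""


class ConfigError(ModelError):
    """Invalid model definition (schema, expression syntax, bad bounds)."""


class UnboundParameterError(ConfigError):
    """An expression references a parameter with no bound value."""

    def __init__(self, name: str):
        self.parameter = name
        super().__init__(f"unbound parameter {name!r}")


class TreeValidationError(ModelError):
    """Structural violation, e.g. chance-node probabilities not summing to 1."""


class UndefinedICERError(ModelError):
    """ICER undefined (equal effectiveness); report dominance or
    cost-minimisation instead of a ratio."""


class CalibrationError(ModelError):
    """Calibration targets are infeasible (e.g. negative implied cost)."""


class NoThresholdError(ModelError):
    """The cost difference does not change sign over the searched bracket."""


# ---------------------------------------------------------------------------
# Expressions
# ---------------------------------------------------------------------------

_ALLOWED_AST = (
    ast.Expression,
    ast.BinOp,
    ast.UnaryOp,
    ast.Add,
    ast.Sub,
    ast.Mult,
    ast.USub,
    ast.UAdd,
    ast.Constant,
    ast.Name,
    ast.Load,
)


class Expr:
    """A restricted arithmetic expression over named parameters.

    Only ``+``, ``-``, ``*``, unary minus, numeric constants and bare
    parameter names are admitted. Instances are callable with a mapping
    of parameter name to value (scalar or numpy array).
    """

    __slots__ = ("source", "names", "_code")

    def __init__(self, source: Union[str, int, float]):
        if isinstance(source, bool) or not isinstance(source, (str, int, float)):
            if not isinstance(source, str):
                raise ConfigError(f"expression must be a string or number, got {source!r}")
        if isinstance(source, (int, float)):
            source = repr(float(source))
        self.source = source
        try:
            parsed = ast.parse(source, mode="eval")
        except SyntaxError as exc:
            raise ConfigError(f"invalid expression {source!r}: {exc}") from None
        for node in ast.walk(parsed):
            if not isinstance(node, _ALLOWED_AST):
                raise ConfigError(
                    f"expression {source!r} uses disallowed construct "
                    f"{type(node).__name__}; only +, -, *, numbers and "
                    f"parameter names are supported"
                )
            if isinstance(node, ast.Constant) and not isinstance(node.value, (int, float)):
                raise ConfigError(f"non-numeric constant in expression {source!r}")
        self.names = frozenset(
            n.id for n in ast.walk(parsed) if isinstance(n, ast.Name)
        )
        self._code = compile(parsed, "<expr>", "eval")

    def __call__(self, env: Mapping[str, Any]):
        missing = self.names.difference(env)
        if missing:
            raise UnboundParameterError(sorted(missing)[0])
        scope = {"__builtins__": {}}
        scope.update({k: env[k] for k in self.names})
        return eval(self._code, scope)  # noqa: S307 - AST whitelisted above

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Expr({self.source!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, Expr) and self.source == other.source

    def __hash__(self) -> int:
        return hash(self.source)


def as_expr(value: Union[str, int, float, Expr]) -> Expr:
    return value if isinstance(value, Expr) else Expr(value)


# ---------------------------------------------------------------------------
# Parameters and payoffs
# ---------------------------------------------------------------------------

class Role(str, Enum):
    COST = "cost"           # USD
    PROBABILITY = "probability"
    EFFECT = "effect"       # dimensionless effect size
    COUNT = "count"         # e.g. number of therapy sessions


@dataclass(frozen=True)
class Parameter:
    """A named model input with base value and plausible low/high range.

    ``distribution`` optionally carries a sampling spec for probabilistic
    sensitivity analysis (see :mod:`oacea.psa`); when absent a default
    triangular(low, base, high) is used.
    """

    name: str
    base: float
    low: float
    high: float
    role: Role
    distribution: Optional[Any] = None

    def __post_init__(self):
        if not (self.low <= self.base <= self.high):
            raise ConfigError(
                f"parameter {self.name!r}: requires low <= base <= high, "
                f"got ({self.low}, {self.base}, {self.high})"
            )
        if self.role is Role.PROBABILITY and not (0.0 <= self.low and self.high <= 1.0):
            raise ConfigError(
                f"probability parameter {self.name!r} must lie within [0, 1]"
            )
        if self.role is Role.COST and self.low < 0:
            raise ConfigError(f"cost parameter {self.name!r} must have low >= 0")


@dataclass(frozen=True)
class PayoffPair:
    """Expected (cost USD, effectiveness) accumulated over the horizon."""

    cost: Any
    effect: Any

    def __iter__(self):
        yield self.cost
        yield self.effect


# ---------------------------------------------------------------------------
# Tree nodes
# ---------------------------------------------------------------------------

class NodeKind(str, Enum):
    DECISION = "decision"
    CHANCE = "chance"
    TERMINAL = "terminal"


@dataclass(frozen=True)
class Branch:
    """An outgoing edge: probability expression (None under a decision
    node) and the child node."""

    prob: Optional[Expr]
    node: "TreeNode"


@dataclass(frozen=True)
class TreeNode:
    kind: NodeKind
    label: str
    children: tuple = ()
    payoff: Optional[tuple] = None  # (cost Expr, effect Expr) for terminals

    # -- constructors -------------------------------------------------------

    @staticmethod
    def terminal(label: str, cost, effect) -> "TreeNode":
        return TreeNode(NodeKind.TERMINAL, label, (), (as_expr(cost), as_expr(effect)))

    @staticmethod
    def chance(label: str, branches: Sequence[tuple]) -> "TreeNode":
        """``branches`` is a sequence of (probability expression, node)."""
        if not branches:
            raise ConfigError(f"chance node {label!r} must have children")
        built = []
        for prob, node in branches:
            if prob is None:
                raise ConfigError(
                    f"chance node {label!r}: every branch needs a probability"
                )
            built.append(Branch(as_expr(prob), node))
        return TreeNode(NodeKind.CHANCE, label, tuple(built))

    @staticmethod
    def decision(label: str, strategies: Sequence["TreeNode"]) -> "TreeNode":
        if not strategies:
            raise ConfigError(f"decision node {label!r} must have children")
        return TreeNode(
            NodeKind.DECISION, label, tuple(Branch(None, n) for n in strategies)
        )

    # -- helpers -------------------------------------------------------------

    @property
    def strategy_labels(self) -> tuple:
        return tuple(b.node.label for b in self.children)

    def parameter_names(self) -> frozenset:
        names = set()
        if self.payoff is not None:
            names |= self.payoff[0].names | self.payoff[1].names
        for branch in self.children:
            if branch.prob is not None:
                names |= branch.prob.names
            names |= branch.node.parameter_names()
        return frozenset(names)

    def terminals(self):
        if self.kind is NodeKind.TERMINAL:
            yield self
        for branch in self.children:
            yield from branch.node.terminals()


# ---------------------------------------------------------------------------
# Rollback
# ---------------------------------------------------------------------------

def rollback(node: TreeNode, params: Mapping[str, Any]):
    """Expected-value evaluation of a (sub)tree.

    Returns a :class:`PayoffPair` for chance/terminal nodes. For a
    decision node, returns a dict mapping each strategy label to its
    rolled-back pair — both strategies are reported, no optimisation is
    performed.

    Parameter values may be scalars or equally shaped numpy arrays (the
    latter evaluates many parameter draws in one pass).
    """
    if node.kind is NodeKind.TERMINAL:
        cost_expr, effect_expr = node.payoff
        return PayoffPair(cost_expr(params), effect_expr(params))

    if node.kind is NodeKind.DECISION:
        return {b.node.label: rollback(b.node, params) for b in node.children}

    # chance node
    probs = [b.prob(params) for b in node.children]
    total = probs[0]
    for p in probs[1:]:
        total = total + p
    err = np.max(np.abs(np.asarray(total) - 1.0))
    if err > PROB_SUM_TOL:
        raise TreeValidationError(
            f"chance node {node.label!r}: branch probabilities deviate from 1 "
            f"by {err:.3g} (tolerance {PROB_SUM_TOL})"
        )
    cost = effect = 0.0
    for p, branch in zip(probs, node.children):
        child = rollback(branch.node, params)
        cost = cost + p * child.cost
        effect = effect + p * child.effect
    return PayoffPair(cost, effect)


# ---------------------------------------------------------------------------
# Incremental cost-effectiveness
# ---------------------------------------------------------------------------

def compute_icer(cost_new: float, cost_std: float,
                 eff_new: float, eff_std: float) -> float:
    """Incremental cost-effectiveness ratio of the new strategy versus
    the standard: (cost_new - cost_std) / (eff_new - eff_std), in USD per
    unit effect size.

    Raises :class:`UndefinedICERError` on equal effectiveness — report a
    dominance classification or plain cost-minimisation instead.
    """
    delta_effect = eff_new - eff_std
    if delta_effect == 0:
        raise UndefinedICERError(
            "equal effectiveness: ICER undefined; report dominance or "
            "compare costs directly"
        )
    return (cost_new - cost_std) / delta_effect


def truncate_dollars(x: float) -> int:
    """Truncate a dollar amount toward zero, the convention used for
    reported ICERs (e.g. 18146.15 -> 18146, -15576.67 -> -15576)."""
    return math.trunc(x)


class Dominance(str, Enum):
    """Sign-pattern classification of (delta_cost, delta_effect), from
    the perspective "new strategy versus standard"."""

    DOMINANT = "dominant"          # cheaper and more effective
    DOMINATED = "dominated"        # costlier and less effective
    NE = "NE"                      # costlier and more effective
    SW = "SW"                      # cheaper and less effective
    EQUAL = "equal"                # identical cost and effect
    EQUAL_COST = "equal_cost"      # same cost, different effect
    EQUAL_EFFECT = "equal_effect"  # same effect, different cost


def classify_dominance(delta_cost: float, delta_effect: float) -> Dominance:
    """Map the sign pattern of the incremental pair onto the
    cost-effectiveness plane. Exhaustive and mutually exclusive over all
    nine sign patterns; exact zeros get dedicated tie categories rather
    than an arbitrary quadrant."""
    if delta_cost == 0 and delta_effect == 0:
        return Dominance.EQUAL
    if delta_cost == 0:
        return Dominance.EQUAL_COST
    if delta_effect == 0:
        return Dominance.EQUAL_EFFECT
    if delta_cost < 0 and delta_effect > 0:
        return Dominance.DOMINANT
    if delta_cost > 0 and delta_effect < 0:
        return Dominance.DOMINATED
    if delta_cost > 0:
        return Dominance.NE
    return Dominance.SW


@dataclass(frozen=True)
class IncrementalResult:
    """Incremental comparison of a new strategy against a standard."""

    delta_cost: float
    delta_effect: float
    icer: Optional[float]
    icer_truncated: Optional[int]
    classification: Dominance

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_effect": self.delta_effect,
            "icer": self.icer,
            "icer_truncated": self.icer_truncated,
            "classification": self.classification.value,
        }


def incremental(new: PayoffPair, std: PayoffPair) -> IncrementalResult:
    """Incremental result for a strategy pair; the ICER is suppressed
    (None) when the effect difference is exactly zero."""
    dc = new.cost - std.cost
    de = new.effect - std.effect
    if de == 0:
        icer = trunc = None
    else:
        icer = dc / de
        trunc = truncate_dollars(icer)
    return IncrementalResult(dc, de, icer, trunc, classify_dominance(dc, de))


# ---------------------------------------------------------------------------
# Payment-rate conversion
# ---------------------------------------------------------------------------

def commercial_rate(medicare_rate: float) -> float:
    """Convert a Medicare payment rate to the implied commercial payer
    rate, assuming Medicare pays 75% of commercial. Uses the exact ratio
    1/0.75 (about $1.33 per Medicare dollar when rounded to cents)."""
    if medicare_rate < 0:
        raise ConfigError("medicare_rate must be non-negative")
    return medicare_rate / MEDICARE_TO_COMMERCIAL_FRACTION
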