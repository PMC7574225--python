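"""Synthetic model generators with known closed-form answers.

Two families, both fully seeded:

* :func:`gen_tree` — random chance trees whose expected payoff is also
  computed at generation time by independent root-to-leaf path
  enumeration, giving an oracle for the rollback algorithm.
* :func:`gen_linear_model` — two-strategy models whose cost difference
  is an explicit linear function of the parameters, giving analytic
  oracles for break-even thresholds (root of the linear form) and
  tornado swings (|coefficient| x range).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

from .model import Model, model_from_config
from .tree import ConfigError, Parameter, PayoffPair, Role, TreeNode

__all__ = ["GeneratedTree", "LinearModel", "gen_tree", "gen_linear_model"]

#: Default payoff ranges, mirroring the USD / effect-size scales of the
#: knee-OA application.
COST_RANGE = (0.0, 10_000.0)
EFFECT_RANGE = (0.0, 1.0)


# ---------------------------------------------------------------------------
# Random chance trees with a path-enumeration oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratedTree:
    root: TreeNode
    parameters: Dict[str, Parameter]
    #: Expected payoff computed by enumerating every root-to-leaf path
    #: and summing path-probability x terminal payoff — an independent
    #: code path from rollback.
    oracle: PayoffPair


def gen_tree(depth: int, branching: int, seed: int,
             cost_range: Tuple[float, float] = COST_RANGE,
             effect_range: Tuple[float, float] = EFFECT_RANGE) -> GeneratedTree:
    """Random chance tree of the given depth and branching factor.

    Branch probabilities are drawn from a flat Dirichlet (so they sum to
    one by construction); terminal payoffs are uniform draws referenced
    through generated parameters. ``depth=1`` yields a single terminal.
    Deterministic given ``seed``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if depth > 1 and branching < 2:
        raise ValueError("branching must be >= 2")
    rng = np.random.default_rng(seed)
    params: Dict[str, Parameter] = {}
    paths = []  # (path probability, cost base, effect base)
    counter = {"terminal": 0, "chance": 0}

    def make(level: int, prob: float) -> TreeNode:
        if level == depth:
            i = counter["terminal"]
            counter["terminal"] += 1
            cost = float(rng.uniform(*cost_range))
            effect = float(rng.uniform(*effect_range))
            c_name, e_name = f"c_{i}", f"e_{i}"
            params[c_name] = Parameter(c_name, cost, cost_range[0], cost_range[1], Role.COST)
            params[e_name] = Parameter(e_name, effect, effect_range[0], effect_range[1], Role.EFFECT)
            paths.append((prob, cost, effect))
            return TreeNode.terminal(f"leaf_{i}", c_name, e_name)
        j = counter["chance"]
        counter["chance"] += 1
        probs = rng.dirichlet(np.ones(branching))
        branches = [
            (repr(float(p)), make(level + 1, prob * float(p))) for p in probs
        ]
        return TreeNode.chance(f"chance_{j}", branches)

    root = make(1, 1.0)
    oracle_cost = sum(p * c for p, c, _ in paths)
    oracle_effect = sum(p * e for p, _, e in paths)
    return GeneratedTree(root, params, PayoffPair(oracle_cost, oracle_effect))


# ---------------------------------------------------------------------------
# Linear two-strategy models with analytic oracles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearModel:
    """A model whose cost difference is delta_cost(x) = intercept +
    sum(coefficient_i * x_i), with the closed form attached."""

    model: Model
    coefficients: Dict[str, float]
    intercept: float

    def delta_cost(self, values: Optional[Mapping[str, float]] = None) -> float:
        vals = {n: self.model.parameters[n].base for n in self.coefficients}
        if values:
            vals.update(values)
        return self.intercept + sum(c * vals[n] for n, c in self.coefficients.items())

    def analytic_threshold(self, parameter: str) -> float:
        """Root of the linear cost difference in one parameter, others
        at base."""
        coef = self.coefficients[parameter]
        if coef == 0:
            raise ZeroDivisionError(f"parameter {parameter!r} has zero coefficient")
        base = self.model.parameters[parameter].base
        return base - self.delta_cost() / coef

    def analytic_swing(self, parameter: str) -> float:
        """Tornado swing: |coefficient| x (high - low)."""
        p = self.model.parameters[parameter]
        return abs(self.coefficients[parameter]) * (p.high - p.low)


def gen_linear_model(coefficients: Mapping[str, float], seed: int = 0,
                     intercept: float = 0.0,
                     ranges: Optional[Mapping[str, Tuple[float, float]]] = None,
                     base_cost: float = 20_000.0) -> LinearModel:
    """Two-strategy model with an explicit linear cost difference.

    Positive-coefficient terms are charged to the "new" arm, negative
    ones to the "standard" arm, and a large shared ``base_cost`` keeps
    both terminal costs non-negative over the parameter ranges. Ranges
    default to unit intervals [0, 1] with the base at the midpoint
    (override per parameter via ``ranges``); effects are fixed constants
    0.6 vs 0.4 so the ICER is defined. Deterministic given ``seed``
    (used only when ranges are drawn in future extensions; kept in the
    signature for interface stability).
    """
    if not coefficients:
        raise ConfigError("at least one coefficient is required")
    if all(c == 0 for c in coefficients.values()):
        raise ConfigError("all-zero coefficients: cost difference is constant")
    ranges = dict(ranges or {})
    params = []
    new_terms, std_terms = [], []
    for name, coef in coefficients.items():
        lo, hi = ranges.get(name, (0.0, 1.0))
        if not lo < hi:
            raise ConfigError(f"invalid range for {name!r}: ({lo}, {hi})")
        # role "count": generic dimensionless drivers, may span negative values
        params.append(dict(name=name, base=(lo + hi) / 2.0, low=lo, high=hi, role="count"))
        if coef > 0:
            new_terms.append(f"{coef!r}*{name}")
        elif coef < 0:
            std_terms.append(f"{-coef!r}*{name}")
    new_cost = " + ".join([repr(base_cost + max(intercept, 0.0))] + new_terms)
    std_cost = " + ".join([repr(base_cost + max(-intercept, 0.0))] + std_terms)
    config = {
        "format_version": 1,
        "name": f"linear_synthetic_{seed}",
        "parameters": params,
        "tree": {
            "kind": "decision",
            "label": "linear",
            "children": [
                {"node": {"kind": "terminal", "label": "new",
                          "cost": new_cost, "effect": 0.6}},
                {"node": {"kind": "terminal", "label": "standard",
                          "cost": std_cost, "effect": 0.4}},
            ],
        },
        "strategies": ["new", "standard"],
    }
    return LinearModel(model_from_config(config), dict(coefficients), float(intercept))
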