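"""Probabilistic sensitivity analysis (PSA) over a decision-tree model.

Each iteration draws every uncertain parameter from its distribution,
rolls the tree back for both strategies of a comparison and records the
incremental (delta_cost, delta_effect) pair. The cloud of pairs is
summarised on the cost-effectiveness plane (x = delta effect, y = delta
cost): quadrant proportions, centroid, and optionally net monetary
benefit (NMB) and a cost-effectiveness acceptability curve (CEAC).

Sampling protocol: a single root seed spawns one independent stream per
sampled parameter, in the model's declared parameter order, so adding or
removing one parameter's uncertainty does not perturb any other
parameter's draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np

from .tree import ConfigError, Parameter, Role, rollback

__all__ = [
    "DistributionSpec",
    "PSAResult",
    "run_psa",
    "quadrant_summary",
    "net_monetary_benefit",
    "ceac",
    "symmetric_triangular_specs",
]

#: Cost-effectiveness plane categories: quadrants by (delta_effect,
#: delta_cost) sign, plus boundary categories for exact zeros (measure
#: zero under continuous distributions but kept explicit).
QUADRANTS = ("NE", "NW", "SE", "SW", "zero_cost", "zero_effect", "origin")


# ---------------------------------------------------------------------------
# Distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution for one parameter.

    kind ``point``: degenerate at ``mode``. kind ``uniform``: on
    (low, high). kind ``triangular``: on (low, high) with mode ``mode``.
    All values are in the underlying parameter's units.
    """

    kind: str
    low: Optional[float] = None
    mode: Optional[float] = None
    high: Optional[float] = None

    def __post_init__(self):
        if self.kind not in ("point", "uniform", "triangular"):
            raise ConfigError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "point":
            if self.mode is None:
                raise ConfigError("point distribution needs a mode value")
        elif self.kind == "uniform":
            if self.low is None or self.high is None or not self.low < self.high:
                raise ConfigError("uniform distribution needs low < high")
        else:
            if None in (self.low, self.mode, self.high) or not (
                self.low <= self.mode <= self.high
            ):
                raise ConfigError("triangular distribution needs low <= mode <= high")

    @staticmethod
    def for_anchors(kind: str, low: float, mode: float, high: float) -> "DistributionSpec":
        """Build a spec from (low, base, high) anchors, collapsing to a
        point mass when the range is degenerate."""
        if kind == "point" or low == high:
            return DistributionSpec("point", mode=mode)
        if kind == "uniform":
            return DistributionSpec("uniform", low=low, high=high)
        return DistributionSpec("triangular", low=low, mode=mode, high=high)

    @staticmethod
    def point(value: float) -> "DistributionSpec":
        return DistributionSpec("point", mode=value)

    @property
    def support(self) -> Tuple[float, float]:
        if self.kind == "point":
            return (self.mode, self.mode)
        return (self.low, self.high)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "point":
            return np.full(n, float(self.mode))
        if self.kind == "uniform":
            return rng.uniform(self.low, self.high, n)
        return rng.triangular(self.low, self.mode, self.high, n)


def default_spec(param: Parameter) -> DistributionSpec:
    """The parameter's declared distribution, else triangular on its
    (low, base, high) anchors (point mass if low == high)."""
    if param.distribution is not None:
        return param.distribution
    return DistributionSpec.for_anchors("triangular", param.low, param.base, param.high)


def _validate_spec(param: Parameter, spec: DistributionSpec) -> None:
    lo, hi = spec.support
    if param.role is Role.PROBABILITY and not (0.0 <= lo and hi <= 1.0):
        raise ConfigError(
            f"distribution for probability parameter {param.name!r} has "
            f"support ({lo}, {hi}) outside [0, 1]"
        )
    if param.role is Role.COST and lo < 0:
        raise ConfigError(
            f"distribution for cost parameter {param.name!r} admits "
            f"negative values"
        )


def symmetric_triangular_specs(model, parameters: Optional[Iterable[str]] = None,
                               ) -> Dict[str, DistributionSpec]:
    """Triangular specs symmetric about each parameter's base value,
    with half-width min(base - low, high - base); parameters with a
    degenerate half-width get a point mass. Symmetric sampling keeps the
    PSA centroid centred on the base case for models multilinear in
    their parameters."""
    names = list(parameters) if parameters is not None else list(model.parameters)
    specs = {}
    for name in names:
        p = model.parameters[name]
        half = min(p.base - p.low, p.high - p.base)
        if half <= 0:
            specs[name] = DistributionSpec.point(p.base)
        else:
            specs[name] = DistributionSpec(
                "triangular", low=p.base - half, mode=p.base, high=p.base + half
            )
    return specs


# ---------------------------------------------------------------------------
# PSA run
# ---------------------------------------------------------------------------

@dataclass
class PSAResult:
    """Per-iteration incremental pairs plus plane summaries."""

    iterations: int
    seed: int
    comparison: Tuple[str, str]
    delta_cost: np.ndarray
    delta_effect: np.ndarray
    quadrant_proportions: Dict[str, float]
    centroid: Tuple[float, float]

    @property
    def pairs(self):
        return list(zip(self.delta_cost.tolist(), self.delta_effect.tolist()))

    def nmb(self, wtp: float) -> np.ndarray:
        return net_monetary_benefit(wtp, self.delta_cost, self.delta_effect)

    def ceac(self, wtps: Sequence[float]) -> Dict[float, float]:
        return ceac(self.delta_cost, self.delta_effect, wtps)

    def summary(self, wtps: Sequence[float] = ()) -> dict:
        out = {
            "iterations": self.iterations,
            "seed": self.seed,
            "comparison": list(self.comparison),
            "quadrant_proportions": self.quadrant_proportions,
            "centroid": {
                "delta_cost": self.centroid[0],
                "delta_effect": self.centroid[1],
            },
        }
        if wtps:
            out["ceac"] = {str(w): v for w, v in self.ceac(wtps).items()}
        return out


def run_psa(model, dists: Optional[Mapping[str, DistributionSpec]] = None,
            n: int = 1000, seed: int = 0, comparison: int = 0,
            sample_only: Optional[Iterable[str]] = None) -> PSAResult:
    """Monte-Carlo PSA: ``n`` joint parameter draws, each evaluated by
    tree rollback for both strategies of the chosen comparison.

    ``dists`` overrides per-parameter distributions (default: the
    parameter's declared spec, else triangular on low/base/high).
    ``sample_only`` restricts sampling to a subset of parameters, the
    rest held at base. Reproducible given (n, seed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    dists = dict(dists or {})
    unknown = set(dists) - set(model.parameters)
    if unknown:
        raise ConfigError(f"distribution for unknown parameter(s): {sorted(unknown)}")
    sampled = list(model.parameters) if sample_only is None else list(sample_only)
    unknown = set(sampled) - set(model.parameters)
    if unknown:
        raise ConfigError(f"sample_only names unknown parameter(s): {sorted(unknown)}")

    specs = {}
    for name in sampled:
        param = model.parameters[name]
        spec = dists.get(name, default_spec(param))
        _validate_spec(param, spec)
        specs[name] = spec

    # One child stream per declared parameter, whether or not it is
    # sampled, so the draw for parameter k never depends on which other
    # parameters carry uncertainty.
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(model.parameters))
    env: Dict[str, Any] = {}
    for child, (name, param) in zip(children, model.parameters.items()):
        if name in specs:
            env[name] = specs[name].sample(np.random.default_rng(child), n)
        else:
            env[name] = param.base

    pairs = rollback(model.root, env)
    new, std = model.comparisons[comparison]
    dc = np.broadcast_to(np.asarray(pairs[new].cost - pairs[std].cost, dtype=float), (n,)).copy()
    de = np.broadcast_to(np.asarray(pairs[new].effect - pairs[std].effect, dtype=float), (n,)).copy()

    return PSAResult(
        iterations=n,
        seed=seed,
        comparison=(new, std),
        delta_cost=dc,
        delta_effect=de,
        quadrant_proportions=quadrant_summary(dc, de),
        centroid=(float(dc.mean()), float(de.mean())),
    )


# ---------------------------------------------------------------------------
# Plane summaries
# ---------------------------------------------------------------------------

def quadrant_summary(delta_cost, delta_effect) -> Dict[str, float]:
    """Fraction of iterations in each region of the cost-effectiveness
    plane. NE: more effective & more costly; SE: more effective &
    cheaper (dominant); NW: less effective & more costly (dominated);
    SW: less effective & cheaper. Exact zeros fall in boundary
    categories. Proportions sum to 1."""
    dc = np.asarray(delta_cost, dtype=float)
    de = np.asarray(delta_effect, dtype=float)
    if dc.size == 0:
        raise ValueError("empty incremental pairs")
    n = dc.size
    counts = {
        "NE": int(np.sum((dc > 0) & (de > 0))),
        "NW": int(np.sum((dc > 0) & (de < 0))),
        "SE": int(np.sum((dc < 0) & (de > 0))),
        "SW": int(np.sum((dc < 0) & (de < 0))),
        "zero_cost": int(np.sum((dc == 0) & (de != 0))),
        "zero_effect": int(np.sum((dc != 0) & (de == 0))),
        "origin": int(np.sum((dc == 0) & (de == 0))),
    }
    return {k: v / n for k, v in counts.items()}


def net_monetary_benefit(wtp: float, delta_cost, delta_effect):
    """NMB = wtp x delta_effect - delta_cost (USD). For delta_effect > 0,
    NMB > 0 at willingness-to-pay ``wtp`` is equivalent to ICER < wtp."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * np.asarray(delta_effect) - np.asarray(delta_cost)


def ceac(delta_cost, delta_effect, wtps: Sequence[float]) -> Dict[float, float]:
    """Cost-effectiveness acceptability curve: fraction of iterations
    with positive NMB at each willingness-to-pay value."""
    dc = np.asarray(delta_cost, dtype=float)
    de = np.asarray(delta_effect, dtype=float)
    return {
        float(w): float(np.mean(net_monetary_benefit(w, dc, de) > 0)) for w in wtps
    }
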