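"""Model-definition config format, schema validation and the runtime
:class:`Model` container.

A model file is YAML (or JSON — YAML is a superset) with sections:

``parameters``
    list of {name, base, low, high, role, distribution?} entries;
    ``distribution`` is an optional {kind: point|uniform|triangular,
    low?, mode?, high?} block, defaulting to triangular anchored at the
    parameter's (low, base, high).
``tree``
    nested node objects. A node has ``kind`` (decision|chance|terminal)
    and ``label``; chance/decision nodes have ``children`` — a list of
    {p: <expression or number>, node: {...}} branches (``p`` omitted
    under a decision node) — and terminals have ``cost`` and ``effect``
    expressions.
``strategies``
    labels of the decision node's children, in order.
``comparisons``
    optional list of [new, standard] label pairs; defaults to the first
    two strategies.

The pydantic schema below is the published contract; call
:func:`config_json_schema` for a JSON-Schema rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Dict, List, Literal, Mapping, Optional, Sequence, Tuple, Union

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .psa import DistributionSpec
from .tree import (
    Branch,
    ConfigError,
    Expr,
    NodeKind,
    Parameter,
    PayoffPair,
    Role,
    TreeNode,
    TreeValidationError,
    incremental,
    rollback,
)

__all__ = [
    "ModelConfig",
    "Model",
    "model_from_config",
    "load_model_file",
    "save_model_file",
    "config_json_schema",
]


# ---------------------------------------------------------------------------
# Pydantic schema for the config file
# ---------------------------------------------------------------------------

class DistributionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["point", "uniform", "triangular"] = "triangular"
    low: Optional[float] = None
    mode: Optional[float] = None
    high: Optional[float] = None


class ParameterConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    base: float
    low: float
    high: float
    role: Literal["cost", "probability", "effect", "count"]
    distribution: Optional[DistributionConfig] = None
    note: Optional[str] = None  # provenance, e.g. "reconstructed"


class BranchConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    p: Optional[Union[str, float]] = None
    node: "NodeConfig"


class NodeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["decision", "chance", "terminal"]
    label: str
    children: Optional[List[BranchConfig]] = None
    cost: Optional[Union[str, float]] = None
    effect: Optional[Union[str, float]] = None

    @model_validator(mode="after")
    def _check_shape(self):
        if self.kind == "terminal":
            if self.children:
                raise ValueError(f"terminal node {self.label!r} cannot have children")
            if self.cost is None or self.effect is None:
                raise ValueError(
                    f"terminal node {self.label!r} needs cost and effect payoffs"
                )
        else:
            if not self.children:
                raise ValueError(f"{self.kind} node {self.label!r} needs children")
            if self.cost is not None or self.effect is not None:
                raise ValueError(
                    f"{self.kind} node {self.label!r} cannot carry payoffs"
                )
            for branch in self.children:
                if self.kind == "chance" and branch.p is None:
                    raise ValueError(
                        f"chance node {self.label!r}: every branch needs a "
                        f"probability expression"
                    )
                if self.kind == "decision" and branch.p is not None:
                    raise ValueError(
                        f"decision node {self.label!r}: strategy branches do "
                        f"not take probabilities"
                    )
        return self


class ModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    format_version: int = 1
    name: str
    description: Optional[str] = None
    parameters: List[ParameterConfig]
    tree: NodeConfig
    strategies: List[str]
    comparisons: Optional[List[Tuple[str, str]]] = None

    @model_validator(mode="after")
    def _check_strategies(self):
        if self.tree.kind != "decision":
            raise ValueError("tree root must be a decision node")
        labels = [b.node.label for b in self.tree.children]
        if self.strategies != labels:
            raise ValueError(
                f"strategies {self.strategies} do not match decision-node "
                f"children {labels}"
            )
        names = {p.name for p in self.parameters}
        if len(names) != len(self.parameters):
            raise ValueError("duplicate parameter names")
        comparisons = self.comparisons or [tuple(self.strategies[:2])]
        for new, std in comparisons:
            for lbl in (new, std):
                if lbl not in self.strategies:
                    raise ValueError(f"comparison references unknown strategy {lbl!r}")
        return self


BranchConfig.model_rebuild()


def config_json_schema() -> dict:
    """JSON-Schema rendering of the model-definition format."""
    return ModelConfig.model_json_schema()


# ---------------------------------------------------------------------------
# Runtime model
# ---------------------------------------------------------------------------

@dataclass
class Model:
    """A validated, evaluable two-(or more-)strategy decision model."""

    name: str
    parameters: Dict[str, Parameter]  # insertion-ordered
    root: TreeNode
    strategies: List[str]
    comparisons: List[Tuple[str, str]]
    config: dict = field(repr=False, default_factory=dict)

    @property
    def base_values(self) -> Dict[str, float]:
        return {name: p.base for name, p in self.parameters.items()}

    def values(self, overrides: Optional[Mapping[str, Any]] = None) -> Dict[str, Any]:
        vals = self.base_values
        if overrides:
            unknown = set(overrides) - set(vals)
            if unknown:
                raise ConfigError(f"unknown parameter(s): {sorted(unknown)}")
            vals.update(overrides)
        return vals

    def evaluate(self, overrides: Optional[Mapping[str, Any]] = None) -> Dict[str, PayoffPair]:
        """Rollback of every strategy at base values (optionally with
        some parameters overridden)."""
        return rollback(self.root, self.values(overrides))

    def incremental(self, comparison: int = 0,
                    overrides: Optional[Mapping[str, Any]] = None):
        new, std = self.comparisons[comparison]
        pairs = self.evaluate(overrides)
        return incremental(pairs[new], pairs[std])

    def with_parameter_base(self, name: str, base: float) -> "Model":
        """Copy of the model with one parameter's base value replaced
        (low/high widened if needed to keep the invariant)."""
        p = self.parameters[name]
        new_p = replace(p, base=base, low=min(p.low, base), high=max(p.high, base))
        params = dict(self.parameters)
        params[name] = new_p
        return replace(self, parameters=params)


# ---------------------------------------------------------------------------
# Config -> runtime conversion
# ---------------------------------------------------------------------------

def _build_node(cfg: NodeConfig) -> TreeNode:
    kind = NodeKind(cfg.kind)
    if kind is NodeKind.TERMINAL:
        return TreeNode.terminal(cfg.label, cfg.cost, cfg.effect)
    if kind is NodeKind.CHANCE:
        return TreeNode.chance(
            cfg.label, [(b.p, _build_node(b.node)) for b in cfg.children]
        )
    return TreeNode.decision(cfg.label, [_build_node(b.node) for b in cfg.children])


def _build_parameter(cfg: ParameterConfig) -> Parameter:
    dist = None
    if cfg.distribution is not None:
        d = cfg.distribution
        dist = DistributionSpec.for_anchors(
            d.kind,
            low=d.low if d.low is not None else cfg.low,
            mode=d.mode if d.mode is not None else cfg.base,
            high=d.high if d.high is not None else cfg.high,
        )
    return Parameter(
        name=cfg.name, base=cfg.base, low=cfg.low, high=cfg.high,
        role=Role(cfg.role), distribution=dist,
    )


def model_from_config(config: Union[dict, ModelConfig]) -> Model:
    """Validate a config mapping against the schema and build the
    runtime model, checking parameter bindings and chance-node
    probability sums at base values."""
    if isinstance(config, ModelConfig):
        cfg = config
    else:
        try:
            cfg = ModelConfig.model_validate(config)
        except ValidationError as exc:
            raise ConfigError(f"model config failed schema validation:\n{exc}") from None
    params = {p.name: _build_parameter(p) for p in cfg.parameters}
    root = _build_node(cfg.tree)
    unbound = root.parameter_names() - set(params)
    if unbound:
        raise ConfigError(
            f"tree references undeclared parameter(s): {sorted(unbound)}"
        )
    comparisons = [tuple(c) for c in (cfg.comparisons or [tuple(cfg.strategies[:2])])]
    model = Model(
        name=cfg.name,
        parameters=params,
        root=root,
        strategies=list(cfg.strategies),
        comparisons=comparisons,
        config=cfg.model_dump(mode="json", exclude_none=True),
    )
    # Surfaces TreeValidationError if probabilities do not sum to 1 at base.
    model.evaluate()
    return model


def load_model_file(path) -> Model:
    """Load and validate a model-definition YAML/JSON file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"model file {path} does not contain a mapping")
    return model_from_config(raw)


def save_model_file(model_or_config: Union[Model, dict], path) -> None:
    """Write a model definition back out as YAML."""
    config = (
        model_or_config.config
        if isinstance(model_or_config, Model)
        else model_or_config
    )
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
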