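"""One-way deterministic sensitivity analysis.

Three tools, all varying a single parameter with every other parameter
held at base: a grid ``sweep`` of the incremental cost/effect, a
bisection ``find_threshold`` for the break-even parameter value at which
the two strategies' expected costs are equal, and a ``tornado`` ranking
of parameters by the swing their (low, high) range induces in the cost
difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, List, Optional, Sequence, Tuple

from .tree import ConfigError, NoThresholdError, Role

__all__ = [
    "SweepPoint",
    "ThresholdResult",
    "TornadoRow",
    "sweep",
    "find_threshold",
    "tornado",
]

#: |delta cost| at which bisection declares break-even, in USD.
COST_TOLERANCE = 0.01
#: Fallback stop: bracket narrowed to this fraction of its initial width.
RELATIVE_WIDTH_TOLERANCE = 1e-6


def _check_parameter(model, parameter: str) -> None:
    if parameter not in model.parameters:
        raise ConfigError(f"unknown parameter {parameter!r}")


def _delta(model, parameter: str, value: float, comparison: int):
    inc = model.incremental(comparison, overrides={parameter: value})
    return inc.delta_cost, inc.delta_effect


# ---------------------------------------------------------------------------
# Sweep
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepPoint:
    value: float
    delta_cost: float
    delta_effect: float


def sweep(model, parameter: str, grid: Sequence[float],
          comparison: int = 0) -> List[SweepPoint]:
    """Evaluate the incremental pair at each grid value of one
    parameter, all others at base."""
    _check_parameter(model, parameter)
    grid = list(grid)
    if not grid:
        raise ValueError("empty grid")
    param = model.parameters[parameter]
    if param.role is Role.PROBABILITY:
        bad = [v for v in grid if not 0.0 <= v <= 1.0]
        if bad:
            raise ConfigError(
                f"grid values {bad} outside [0, 1] for probability "
                f"parameter {parameter!r}"
            )
    return [SweepPoint(v, *_delta(model, parameter, v, comparison)) for v in grid]


# ---------------------------------------------------------------------------
# Break-even threshold
# ---------------------------------------------------------------------------

class ThresholdDirection(str, Enum):
    BELOW_MAKES_NEW_CHEAPER = "below_makes_new_cheaper"
    ABOVE_MAKES_NEW_CHEAPER = "above_makes_new_cheaper"


@dataclass(frozen=True)
class ThresholdResult:
    """Break-even value of one parameter at which the strategies'
    expected costs are equal."""

    parameter: str
    threshold: float
    direction: ThresholdDirection
    bracket: Tuple[float, float]
    delta_cost_at_threshold: float

    @property
    def threshold_rounded(self) -> int:
        """Whole-dollar (or whole-unit) presentation of the threshold."""
        return round(self.threshold)


def find_threshold(model, parameter: str, bracket: Tuple[float, float],
                   comparison: int = 0,
                   cost_tolerance: float = COST_TOLERANCE) -> ThresholdResult:
    """Bisection for the break-even parameter value.

    Requires the cost difference to change sign across the bracket;
    otherwise raises :class:`NoThresholdError` (no silent clamping).
    Stops when |delta cost| <= ``cost_tolerance`` (USD) or the bracket
    has shrunk to 1e-6 of its initial width.
    """
    _check_parameter(model, parameter)
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise ValueError(f"invalid bracket {bracket}")

    f_lo = _delta(model, parameter, lo, comparison)[0]
    f_hi = _delta(model, parameter, hi, comparison)[0]

    if f_lo == 0.0:
        mid, f_mid = lo, f_lo
    elif f_hi == 0.0:
        mid, f_mid = hi, f_hi
    elif f_lo * f_hi > 0:
        raise NoThresholdError(
            f"delta cost does not change sign over {bracket} for "
            f"parameter {parameter!r} (f(lo)={f_lo:.2f}, f(hi)={f_hi:.2f})"
        )
    else:
        a, fa, b = lo, f_lo, hi
        width0 = hi - lo
        mid, f_mid = a, fa
        while b - a > RELATIVE_WIDTH_TOLERANCE * width0:
            mid = 0.5 * (a + b)
            f_mid = _delta(model, parameter, mid, comparison)[0]
            if abs(f_mid) <= cost_tolerance:
                break
            if fa * f_mid < 0:
                b = mid
            else:
                a, fa = mid, f_mid

    # Which side of the threshold makes the new strategy the cheaper one:
    # negative delta cost on the low side means "below makes new cheaper".
    if f_lo < f_hi:
        direction = ThresholdDirection.BELOW_MAKES_NEW_CHEAPER
    else:
        direction = ThresholdDirection.ABOVE_MAKES_NEW_CHEAPER

    return ThresholdResult(
        parameter=parameter,
        threshold=float(mid),
        direction=direction,
        bracket=(lo, hi),
        delta_cost_at_threshold=float(f_mid),
    )


# ---------------------------------------------------------------------------
# Tornado
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TornadoRow:
    parameter: str
    delta_cost_at_low: float
    delta_cost_at_high: float

    @property
    def swing(self) -> float:
        return abs(self.delta_cost_at_high - self.delta_cost_at_low)


def tornado(model, parameters: Optional[Iterable[str]] = None,
            comparison: int = 0) -> List[TornadoRow]:
    """One-way swing of the cost difference over each parameter's
    (low, high) range, others at base; rows sorted by swing descending,
    ties broken alphabetically by parameter name."""
    names = list(parameters) if parameters is not None else list(model.parameters)
    rows = []
    for name in names:
        _check_parameter(model, name)
        p = model.parameters[name]
        dc_low = _delta(model, name, p.low, comparison)[0]
        dc_high = _delta(model, name, p.high, comparison)[0]
        rows.append(TornadoRow(name, dc_low, dc_high))
    return sorted(rows, key=lambda r: (-r.swing, r.parameter))
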