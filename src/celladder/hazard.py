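"""Division hazards: sharp threshold versus a soft (probabilistic) rule.

The adder property holds exactly only for the sharp threshold, where
division cannot fire before the protein count reaches X.  The soft
variant assigns a finite division propensity ``h(x) = c (x/X)**H`` per
unit time, monotonically increasing in the copy number and converging
pointwise to the sharp rule as the steepness H grows (for x != X).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .params import DomainError

__all__ = ["SharpThreshold", "SoftThreshold", "division_hazard"]

_LOG_HUGE = 700.0  # beyond this, exp() overflows; treat as immediate firing


@dataclass(frozen=True)
class SharpThreshold:
    X: int


@dataclass(frozen=True)
class SoftThreshold:
    X: int
    H: float
    c: float = 1.0


def division_hazard(h_spec, x: int) -> float:
    """Division propensity (per unit time) at protein count x.

    Sharp rule: 0 below the threshold, ``inf`` (immediate division) at or
    above it.  Soft rule: ``c * (x / X)**H`` for x >= 1, zero at x = 0,
    computed in log space to stay finite for extreme steepness.
    """
    if x < 0:
        raise DomainError("protein count must be non-negative")
    if isinstance(h_spec, SharpThreshold):
        return math.inf if x >= h_spec.X else 0.0
    if isinstance(h_spec, SoftThreshold):
        if x == 0:
            return 0.0
        log_h = math.log(h_spec.c) + h_spec.H * math.log(x / h_spec.X)
        if log_h > _LOG_HUGE:
            return math.inf
        return math.exp(log_h)
    raise DomainError(f"unknown hazard specification {h_spec!r}")
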