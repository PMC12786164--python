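"""Shelf-life prediction from fitted kinetic and Arrhenius parameters.

Given a fitted reaction order, a rate constant (or an Arrhenius model that
supplies one at any temperature) and a user-chosen acceptability limit on the
normalized quality scale, these routines invert the kinetic law to the time
at which the limit is reached:

* zero order:   t = |1 - A_lim| / k
* first order:  t = |ln A_lim| / k

Acceptability limits are deliberately *mandatory* inputs: where a quality
index stops being acceptable is a product/market decision, not something the
kinetics determine, so no default is shipped.

For non-isothermal storage (cold-chain scenarios) a piecewise-constant
temperature profile is integrated exactly: both pseudo-orders accumulate
degradation linearly in time within a segment (on the original scale for
zero order, in log space for first order), so the crossing time inside the
crossing segment follows by linear interpolation — no ODE solver is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .arrhenius import ArrheniusFit, predict_k
from .errors import DomainError, UnreachableLimitError

UNREACHABLE = math.inf

__all__ = [
    "QualityLimit",
    "TemperatureProfile",
    "UNREACHABLE",
    "time_to_limit",
    "time_to_limit_at_T",
    "integrate_profile",
]


@dataclass(frozen=True)
class QualityLimit:
    """Acceptability threshold on the normalized quality scale.

    ``limit_norm`` is the normalized value at which the product stops being
    acceptable; ``side`` says whether the limit is approached from above
    (decaying attribute, limit < 1) or from below (rising attribute,
    limit > 1).
    """

    attribute: str
    limit_norm: float
    side: str  # "from_above" | "from_below"

    def __post_init__(self) -> None:
        if self.limit_norm <= 0:
            raise DomainError("limit_norm must be positive")
        if self.side not in ("from_above", "from_below"):
            raise DomainError("side must be 'from_above' or 'from_below'")
        if self.side == "from_above" and self.limit_norm >= 1:
            raise UnreachableLimitError(
                "a limit reached from above must lie below the starting value 1"
            )
        if self.side == "from_below" and self.limit_norm <= 1:
            raise UnreachableLimitError(
                "a limit reached from below must lie above the starting value 1"
            )


@dataclass(frozen=True)
class TemperatureProfile:
    """Piecewise-constant storage profile: (duration_days, temperature_K)."""

    segments: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise DomainError("profile needs at least one segment")
        for dur, temp in self.segments:
            if dur <= 0:
                raise DomainError("segment durations must be positive")
            if temp <= 0:
                raise DomainError("segment temperatures must be positive (Kelvin)")

    @property
    def total_duration(self) -> float:
        return sum(d for d, _ in self.segments)

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[float, float]]) -> "TemperatureProfile":
        return cls(tuple((float(d), float(t)) for d, t in pairs))


def _required_degradation(order: int, direction: int, limit: QualityLimit) -> float:
    """Degradation budget D on the working scale: k * t_cross = D."""
    rising = limit.side == "from_below"
    if (direction > 0) != rising:
        raise UnreachableLimitError(
            "limit lies on the wrong side for the fitted direction of change"
        )
    if order == 0:
        return abs(1.0 - limit.limit_norm)
    if order == 1:
        return abs(math.log(limit.limit_norm))
    raise DomainError(f"unsupported order {order}")


def time_to_limit(
    order: int, k: float, direction: int, limit: QualityLimit
) -> float:
    """Days until the normalized quality crosses the acceptability limit.

    Zero order gives t = |1 - limit| / k; first order t = |ln limit| / k.
    Returns ``math.inf`` when k is zero (limit never reached).
    """
    budget = _required_degradation(order, direction, limit)
    if k < 0:
        raise DomainError("rate constant must be nonnegative")
    if k == 0:
        return UNREACHABLE
    return budget / k


def time_to_limit_at_T(
    fit: ArrheniusFit,
    order: int,
    direction: int,
    limit: QualityLimit,
    temperature_K: float,
) -> float:
    """Shelf life at a constant temperature via the Arrhenius model.

    Evaluates k at ``temperature_K`` from the fitted model and inverts the
    kinetic law; strictly decreasing in temperature when Ea > 0.
    """
    k = predict_k(fit, temperature_K)
    return time_to_limit(order, k, direction, limit)


def integrate_profile(
    fit: ArrheniusFit,
    order: int,
    direction: int,
    limit: QualityLimit,
    profile: TemperatureProfile,
) -> float:
    """Shelf life over a piecewise-constant temperature profile.

    Accumulates k_i * dt_i segment by segment on the working scale and
    interpolates the exact crossing time inside the crossing segment.
    Returns ``math.inf`` if the degradation budget is not exhausted by the
    profile's end.
    """
    budget = _required_degradation(order, direction, limit)
    accumulated = 0.0
    elapsed = 0.0
    for duration, temp in profile.segments:
        k = predict_k(fit, temp)
        gain = k * duration
        if accumulated + gain >= budget:
            if gain == 0:
                return UNREACHABLE
            return elapsed + (budget - accumulated) / k
        accumulated += gain
        elapsed += duration
    return UNREACHABLE
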