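"""Environment-dependent linear two-strategy games.

The strategic side of an eco-evolutionary game is a 2x2 matrix game whose
payoffs interpolate linearly between a *poor* environment (state ``n = 0``)
and a *rich* environment (``n = 1``)::

    Pi(n) = (1 - n) * [[R0, S0],   + n * [[R1, S1],
                       [T0, P0]]          [T1, P1]]

Rows and columns are ordered (L, H), where L is the strategy with low
environmental impact and ``x`` denotes the frequency of L players.  Because
two-strategy replicator dynamics depend only on the payoff *difference*
``pi_L - pi_H``, the game is completely characterised by four incentive
parameters:

* ``deltaL1`` -- incentive to *lead a gold rush*: switch to the high-impact
  strategy in a rich environment when everyone else plays L (``T1 - R1``).
* ``deltaH1`` -- incentive to *follow a gold rush*: switch to high impact in
  a rich environment when everyone else already has (``P1 - S1``).
* ``dL0`` -- incentive to *follow an environmental movement*: switch to low
  impact in a poor environment when everyone else already has (``R0 - T0``).
* ``dH0`` -- incentive to *lead an environmental movement*: switch to low
  impact in a poor environment when everyone else plays H (``S0 - P0``).

The signs of ``deltaL1`` and ``dH0`` (the two *leading* incentives) select
the qualitative dynamical regime; see :mod:`ecogames.equilibria`.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from .errors import DomainError

__all__ = [
    "PayoffStructure",
    "IncentiveParams",
    "incentives_from_payoffs",
    "canonical_payoffs",
    "gain",
]


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise DomainError(f"{name} must be a finite real number, got {value!r}")
    return value


@dataclass(frozen=True)
class PayoffStructure:
    """The eight payoff entries of an environment-dependent 2x2 game.

    Subscript 0 denotes the poor environment (``n = 0``), subscript 1 the
    rich environment (``n = 1``).  Entries follow the usual (R, S, T, P)
    naming with row/column order (L, H): R is L-vs-L, S is L-vs-H, T is
    H-vs-L and P is H-vs-H.
    """

    R0: float
    S0: float
    T0: float
    P0: float
    R1: float
    S1: float
    T1: float
    P1: float

    def __post_init__(self) -> None:
        for name in ("R0", "S0", "T0", "P0", "R1", "S1", "T1", "P1"):
            object.__setattr__(self, name, _require_finite(name, getattr(self, name)))

    def matrix(self, n: float) -> np.ndarray:
        """The 2x2 payoff matrix ``Pi(n)`` at environmental state ``n``."""
        n = float(n)
        if not 0.0 <= n <= 1.0:
            raise DomainError(f"environmental state n must lie in [0, 1], got {n}")
        m0 = np.array([[self.R0, self.S0], [self.T0, self.P0]])
        m1 = np.array([[self.R1, self.S1], [self.T1, self.P1]])
        return (1.0 - n) * m0 + n * m1

    def payoffs(self, x: float, n: float) -> tuple[float, float]:
        """Expected payoffs ``(pi_L, pi_H)`` against a population with a
        fraction ``x`` of L players at environmental state ``n``."""
        x = float(x)
        if not 0.0 <= x <= 1.0:
            raise DomainError(f"strategy frequency x must lie in [0, 1], got {x}")
        m = self.matrix(n)
        pi_l = x * m[0, 0] + (1.0 - x) * m[0, 1]
        pi_h = x * m[1, 0] + (1.0 - x) * m[1, 1]
        return pi_l, pi_h

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "PayoffStructure":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class IncentiveParams:
    """The four incentives to lead or follow strategy change.

    No sign constraints apply: the signs place the system in one of the
    four qualitative quadrants of the regime diagram.
    """

    deltaL1: float
    deltaH1: float
    dL0: float
    dH0: float

    def __post_init__(self) -> None:
        for name in ("deltaL1", "deltaH1", "dL0", "dH0"):
            object.__setattr__(self, name, _require_finite(name, getattr(self, name)))

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "IncentiveParams":
        return cls(**json.loads(text))


def incentives_from_payoffs(p: PayoffStructure) -> IncentiveParams:
    """Reduce a payoff structure to its four incentive parameters.

    ``deltaL1 = T1 - R1``, ``deltaH1 = P1 - S1``, ``dL0 = R0 - T0`` and
    ``dH0 = S0 - P0``.  These are the corner values of the payoff-difference
    function and determine the replicator dynamics completely.
    """
    return IncentiveParams(
        deltaL1=p.T1 - p.R1,
        deltaH1=p.P1 - p.S1,
        dL0=p.R0 - p.T0,
        dH0=p.S0 - p.P0,
    )


def canonical_payoffs(inc: IncentiveParams) -> PayoffStructure:
    """A representative payoff structure realising the given incentives.

    Infinitely many payoff matrices share the same incentives (replicator
    dynamics are invariant to column-wise payoff shifts); this canonical
    choice pins the H-row to zero: ``T0 = P0 = T1 = P1 = 0``, so
    ``R0 = dL0``, ``S0 = dH0``, ``R1 = -deltaL1``, ``S1 = -deltaH1``.
    Round-trips exactly through :func:`incentives_from_payoffs`.
    """
    return PayoffStructure(
        R0=inc.dL0,
        S0=inc.dH0,
        T0=0.0,
        P0=0.0,
        R1=-inc.deltaL1,
        S1=-inc.deltaH1,
        T1=0.0,
        P1=0.0,
    )


def gain(x, n, inc: IncentiveParams):
    """Payoff advantage ``g(x, n) = pi_L - pi_H`` of the low-impact strategy.

    Bilinear in ``(x, n)``::

        g(x, n) = (1 - n) * (x * dL0 + (1 - x) * dH0)
                      - n * (x * deltaL1 + (1 - x) * deltaH1)

    with corner values ``g(1, 1) = -deltaL1``, ``g(0, 1) = -deltaH1``,
    ``g(1, 0) = dL0`` and ``g(0, 0) = dH0``.  Accepts scalars or NumPy
    arrays (broadcast together).

    Raises
    ------
    DomainError
        If any ``x`` or ``n`` lies outside ``[0, 1]``.
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise DomainError("strategy frequency x must lie in [0, 1]")
    if np.any(n < 0.0) or np.any(n > 1.0):
        raise DomainError("environmental state n must lie in [0, 1]")
    value = _gain_unchecked(x, n, inc)
    if value.ndim == 0:
        return float(value)
    return value


def _gain_unchecked(x, n, inc: IncentiveParams):
    """Bilinear gain without domain checks; used by solvers whose trial
    steps may momentarily leave the unit square."""
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    return (1.0 - n) * (x * inc.dL0 + (1.0 - x) * inc.dH0) - n * (
        x * inc.deltaL1 + (1.0 - x) * inc.deltaH1
    )


def gain_gradient(x, n, inc: IncentiveParams) -> tuple[float, float]:
    """Exact partial derivatives ``(dg/dx, dg/dn)`` of the bilinear gain."""
    x = float(x)
    n = float(n)
    gx = (1.0 - n) * (inc.dL0 - inc.dH0) - n * (inc.deltaL1 - inc.deltaH1)
    gn = -(x * inc.dL0 + (1.0 - x) * inc.dH0) - (
        x * inc.deltaL1 + (1.0 - x) * inc.deltaH1
    )
    return gx, gn
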