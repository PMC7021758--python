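"""Worked application models mapped onto the incentive framework.

* Common-pool resource harvesting: profit-driven choice between high and
  low harvest effort on a logistically renewing stock.  Linear profits pin
  the incentives to the boundary of the cycle-permitting region, so the
  only outcome (under the textbook profit signs) is a stable mix of
  harvesting strategies -- never cycles.
* Grass-legume competition: nitrogen-fixing legumes versus grasses, argued
  purely through sign and ordering constraints on the incentives, which
  place the system in the cycle-capable region whenever the feedback
  through soil nitrogen is slow enough.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .environments import RenewingResource
from .equilibria import RegimeReport, classify_regime, epsilon_crit
from .errors import DomainError
from .games import IncentiveParams, PayoffStructure

__all__ = [
    "CommonPoolParams",
    "common_pool_incentives",
    "common_pool_payoffs",
    "common_pool_environment",
    "common_pool_outcome",
    "GrassLegumeReport",
    "grass_legume_susceptibility",
]


@dataclass(frozen=True)
class CommonPoolParams:
    """Bioeconomic parameters of a two-effort common-pool harvest.

    Profit per unit effort is ``p*q*eta - w`` at resource level ``eta``:
    ``p`` is the unit price of harvest, ``q`` the harvest efficiency and
    ``w`` the marginal cost of effort.  The stock grows logistically
    (rate ``r``, capacity ``k``) and is harvested at effort ``eL`` or
    ``eH`` with ``eL < eH < r/q``.
    """

    p: float
    q: float
    w: float
    eL: float
    eH: float
    r: float
    k: float

    def __post_init__(self) -> None:
        for name in ("p", "q", "w", "eH", "r", "k"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0.0):
                raise DomainError(f"{name} must be positive, got {v!r}")
        if not (0.0 <= self.eL < self.eH < self.r / self.q):
            raise DomainError("efforts must satisfy 0 <= eL < eH < r/q")

    @property
    def stock_L(self) -> float:
        """Equilibrium stock under pure low effort: ``k*(1 - q*eL/r)``."""
        return self.k * (1.0 - self.q * self.eL / self.r)

    @property
    def stock_H(self) -> float:
        return self.k * (1.0 - self.q * self.eH / self.r)

    def profit(self, effort: float, eta: float) -> float:
        """Harvest profit ``p*q*eta*e - w*e``."""
        return (self.p * self.q * eta - self.w) * effort


def common_pool_incentives(cp: CommonPoolParams) -> IncentiveParams:
    """Incentive parameters of the common-pool harvesting game.

    With equilibrium stocks ``eta_L = k*(1 - q*eL/r)`` (rich state, n=1)
    and ``eta_H = k*(1 - q*eH/r)`` (poor state, n=0)::

        deltaL1 = deltaH1 = (p*q*eta_L - w) * (eH - eL)
        dL0     = dH0     = (w - p*q*eta_H) * (eH - eL)

    Both pairs are positive exactly when profit is positive at the pure-L
    stock and negative at the pure-H stock.  Because lead and follow
    incentives coincide, the output always sits exactly on the boundary
    ``deltaH1 * dL0 = deltaL1 * dH0`` of the cycle-permitting region: no
    positive feedback speed produces cycles in this model.
    """
    de = cp.eH - cp.eL
    delta = (cp.p * cp.q * cp.stock_L - cp.w) * de
    d0 = (cp.w - cp.p * cp.q * cp.stock_H) * de
    return IncentiveParams(deltaL1=delta, deltaH1=delta, dL0=d0, dH0=d0)


def common_pool_payoffs(cp: CommonPoolParams) -> PayoffStructure:
    """Payoff-matrix route to the same game: evaluate the profit function
    at the stocks associated with the two environmental extremes.  An
    individual's profit depends on her own effort and the stock only, so
    rows are constant across opponents."""
    piL0 = cp.profit(cp.eL, cp.stock_H)
    piH0 = cp.profit(cp.eH, cp.stock_H)
    piL1 = cp.profit(cp.eL, cp.stock_L)
    piH1 = cp.profit(cp.eH, cp.stock_L)
    return PayoffStructure(R0=piL0, S0=piL0, T0=piH0, P0=piH0,
                           R1=piL1, S1=piL1, T1=piH1, P1=piH1)


def common_pool_environment(cp: CommonPoolParams, epsilon: float = 1.0) -> RenewingResource:
    """The renewing-resource environment of the harvesting model."""
    return RenewingResource(r=cp.r, k=cp.k, q=cp.q, eL=cp.eL, eH=cp.eH,
                            epsilon=epsilon)


def common_pool_outcome(cp: CommonPoolParams, epsilon: float) -> RegimeReport:
    """Long-run outcome of the common-pool system at feedback speed
    ``epsilon``.

    Under the textbook profit signs (positive profit at the pure-L stock,
    negative at the pure-H stock) all four incentives are positive and sit
    on the cycle-region boundary, so the outcome is a stable mix of
    strategies for *every* ``epsilon > 0`` and the Hopf threshold does not
    exist.  Other profit-sign cases are delegated to the general regime
    classifier without that guarantee.
    """
    inc = common_pool_incentives(cp)
    profit_L = cp.p * cp.q * cp.stock_L - cp.w
    profit_H = cp.p * cp.q * cp.stock_H - cp.w
    env = common_pool_environment(cp, epsilon)
    if profit_L > 0.0 > profit_H:
        return RegimeReport(
            panel="b",
            regime="stable_coexistence",
            epsilon=epsilon,
            epsilon_crit=epsilon_crit(inc, env),  # None: on the boundary
            conditions={
                "profit_at_stock_L": profit_L,
                "profit_at_stock_H": profit_H,
                "on_cycle_boundary": True,
            },
        )
    return classify_regime(inc, epsilon, env)


@dataclass
class GrassLegumeReport:
    """Outcome of the grass-legume ordering checks."""

    susceptible: bool
    failed: list[str] = field(default_factory=list)
    epsilon_crit: Optional[float] = None


def grass_legume_susceptibility(
    inc: IncentiveParams, env=None
) -> GrassLegumeReport:
    """Is a grass-legume system with these incentives susceptible to
    cycles?

    The ecological argument is by orderings, not mechanism: legumes invade
    nitrogen-poor grass swards and grasses invade nitrogen-rich legume
    stands (all four incentives positive), and establishing as the first
    invader is harder than spreading once established (``deltaL1 <
    deltaH1`` and ``dH0 < dL0``).  Together these force the follower
    product to exceed the leader product, so cycles occur whenever the
    nitrogen feedback is slow enough.  The report names any violated
    condition; when all hold and an environment is supplied, the Hopf
    threshold is attached.
    """
    failed = []
    for name in ("deltaL1", "deltaH1", "dL0", "dH0"):
        if not getattr(inc, name) > 0.0:
            failed.append(f"{name} > 0")
    if not inc.deltaL1 < inc.deltaH1:
        failed.append("deltaL1 < deltaH1 (first invader has it harder)")
    if not inc.dH0 < inc.dL0:
        failed.append("dH0 < dL0 (first invader has it harder)")
    report = GrassLegumeReport(susceptible=not failed, failed=failed)
    if report.susceptible and env is not None:
        report.epsilon_crit = epsilon_crit(inc, env)
    return report
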