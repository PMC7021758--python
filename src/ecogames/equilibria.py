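"""Fixed points, stability, Hopf threshold and regime classification.

For renewing and decaying environments the sign of ``dn/dt`` is the sign of
``x - n``, so the line ``n = x`` is the attracting environmental nullcline
and every fixed point lies on it.  The system has up to four equilibria:

* the monomorphic corners ``(0, 0)`` and ``(1, 1)``;
* up to two interior coexistence equilibria, the roots in ``(0, 1)`` of the
  quadratic ``q(x) = g(x, x)``:

      q(x) = dH0*(1-x)^2 + (dL0 - deltaH1)*x*(1-x) - deltaL1*x^2

  The root at which the Jacobian determinant is negative is the saddle
  ``x_plus`` (never stable); the other, ``x_minus``, can be a stable or
  unstable node/focus.

``x_minus`` loses stability in a Hopf bifurcation as the environmental
timescale ratio ``epsilon`` decreases through ``epsilon_crit``: slow
environmental feedback destabilises coexistence into a limit cycle.
Instability additionally requires the follower incentives to be positive in
aggregate and strong relative to the leader incentives:

    deltaH1 + dL0 > 0          (aggregate follower incentive)
    deltaH1 * dL0 > deltaL1 * dH0   (followers outweigh leaders)

The qualitative regime is organised by the signs of the two *leading*
incentives ``deltaL1`` and ``dH0`` (the four panels of the regime diagram),
refined within each panel by edge stability, the interior roots, the two
inequalities above, and ``epsilon`` versus ``epsilon_crit``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .cycles import diagnose_attractor
from .dynamics import EcoEvoSystem, integrate
from .environments import DecayingResource, Environment, RenewingResource
from .errors import DegenerateSystemError, DomainError
from .games import IncentiveParams, _gain_unchecked, gain_gradient

__all__ = [
    "Equilibrium",
    "RegimeReport",
    "nullcline_quadratic",
    "interior_equilibria",
    "all_equilibria",
    "jacobian",
    "classify_equilibrium",
    "epsilon_crit",
    "classify_regime",
    "equilibria_table",
]

#: strict inequalities closer to equality than this are treated as degenerate
DEGENERACY_TOL = 1e-9

_EDGE_KINDS = {"edge_poor": (0.0, 0.0), "edge_rich": (1.0, 1.0)}


@dataclass
class Equilibrium:
    """A fixed point ``(x_star, n_star)`` with its linearisation."""

    x_star: float
    n_star: float
    kind: str  # edge_poor | edge_rich | interior_plus | interior_minus
    eigenvalues: Optional[tuple[complex, complex]] = None
    label: Optional[str] = None  # stable_node | stable_focus | unstable_node
    #                            | unstable_focus | saddle | nonhyperbolic

    @property
    def is_stable(self) -> bool:
        return self.label in ("stable_node", "stable_focus")


@dataclass
class RegimeReport:
    """Qualitative long-run classification of an eco-evolutionary system."""

    panel: str  # a | b | c | d  (quadrant of the leading-incentive signs)
    regime: str
    epsilon: float
    epsilon_crit: Optional[float] = None
    conditions: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "panel": self.panel,
                "regime": self.regime,
                "epsilon": self.epsilon,
                "epsilon_crit": self.epsilon_crit,
                "conditions": self.conditions,
            },
            indent=2,
        )


def _check_family(env: Environment) -> None:
    if not isinstance(env, (RenewingResource, DecayingResource)):
        raise DomainError(
            "analytic equilibrium enumeration applies to renewing/decaying "
            "environments (tipping environments are probed by simulation)"
        )


def nullcline_quadratic(inc: IncentiveParams) -> tuple[float, float, float]:
    """Coefficients ``(a, b, c)`` of ``q(x) = g(x, x) = a*x^2 + b*x + c``."""
    a = inc.dH0 - (inc.dL0 - inc.deltaH1) - inc.deltaL1
    b = -2.0 * inc.dH0 + inc.dL0 - inc.deltaH1
    c = inc.dH0
    return a, b, c


def _nullcline_roots(inc: IncentiveParams) -> list[float]:
    a, b, c = nullcline_quadratic(inc)
    scale = max(abs(a), abs(b), abs(c))
    if scale == 0.0:
        raise DegenerateSystemError(
            "g(x, x) vanishes identically: the environmental nullcline is a "
            "continuum of fixed points, not a finite equilibrium set"
        )
    if abs(a) <= 1e-14 * scale:
        if abs(b) <= 1e-14 * scale:
            return []  # constant nonzero q: no roots
        roots = [-c / b]
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0.0:
            return []
        sq = math.sqrt(disc)
        # numerically stable quadratic roots
        qq = -0.5 * (b + math.copysign(sq, b)) if b != 0.0 else 0.5 * sq
        if qq == 0.0:
            roots = [0.0]
        else:
            roots = sorted({qq / a, c / qq})
    eps = 1e-12
    return sorted(r for r in roots if eps < r < 1.0 - eps)


def interior_equilibria(inc: IncentiveParams) -> list[Equilibrium]:
    """The 0-2 coexistence equilibria on the nullcline ``n = x``.

    Kinds are assigned by the saddle property, not by root order: the
    Jacobian determinant at an interior fixed point has the opposite sign
    of ``q'(x)`` (up to positive factors), so the root with ``q'(x) > 0``
    is the saddle ``interior_plus``.

    Raises
    ------
    DegenerateSystemError
        If ``q`` vanishes identically (a continuum of fixed points).
    """
    roots = _nullcline_roots(inc)
    a, b, _ = nullcline_quadratic(inc)
    out = []
    for r in roots:
        slope = 2.0 * a * r + b  # q'(r) = g_x + g_n at (r, r)
        kind = "interior_plus" if slope > 0.0 else "interior_minus"
        out.append(Equilibrium(x_star=r, n_star=r, kind=kind))
    return out


def all_equilibria(sys: EcoEvoSystem) -> list[Equilibrium]:
    """All fixed points of a renewing/decaying system, classified."""
    _check_family(sys.environment)
    eqs = [
        Equilibrium(0.0, 0.0, "edge_poor"),
        Equilibrium(1.0, 1.0, "edge_rich"),
    ]
    eqs.extend(interior_equilibria(sys.incentives))
    return [classify_equilibrium(sys, eq) for eq in eqs]


def jacobian(sys: EcoEvoSystem, x: float, n: float) -> np.ndarray:
    """Exact Jacobian of the vector field at ``(x, n)``.

    The gain is bilinear and the environmental drifts are polynomial in the
    state, so all partials are closed-form.
    """
    x = float(x)
    n = float(n)
    if not (0.0 <= x <= 1.0 and 0.0 <= n <= 1.0):
        raise DomainError(f"state ({x}, {n}) lies outside the unit square")
    inc = sys.incentives
    g = float(_gain_unchecked(x, n, inc))
    gx, gn = gain_gradient(x, n, inc)
    j11 = (1.0 - 2.0 * x) * g + x * (1.0 - x) * gx
    j12 = x * (1.0 - x) * gn
    j21, j22 = sys.environment.drift_gradient(x, n)
    return np.array([[j11, j12], [j21, j22]])


def classify_equilibrium(sys: EcoEvoSystem, eq: Equilibrium) -> Equilibrium:
    """Fill in eigenvalues and a stability label for a fixed point.

    ``det < 0`` is a saddle; otherwise the sign of the largest eigenvalue
    real part decides stability, with node/focus split by whether the
    eigenvalues are complex.  Within ``1e-9`` of a zero real part (or zero
    determinant) the point is reported ``nonhyperbolic``.
    """
    dx, dn = sys.field(eq.x_star, eq.n_star)
    if math.hypot(float(dx), float(dn)) >= 1e-10:
        raise DomainError(
            f"({eq.x_star}, {eq.n_star}) is not a fixed point "
            f"(|field| = {math.hypot(float(dx), float(dn)):.2e})"
        )
    jac = jacobian(sys, eq.x_star, eq.n_star)
    eigs = np.linalg.eigvals(jac)
    det = float(np.linalg.det(jac))
    max_re = float(np.max(eigs.real))
    is_complex = bool(np.max(np.abs(eigs.imag)) > 1e-12)

    if det < -DEGENERACY_TOL:
        label = "saddle"
    elif abs(max_re) < DEGENERACY_TOL or abs(det) <= DEGENERACY_TOL:
        label = "nonhyperbolic"
    elif max_re < 0.0:
        label = "stable_focus" if is_complex else "stable_node"
    else:
        label = "unstable_focus" if is_complex else "unstable_node"

    eq.eigenvalues = (complex(eigs[0]), complex(eigs[1]))
    eq.label = label
    return eq


def _x_minus(inc: IncentiveParams) -> Optional[Equilibrium]:
    for eq in interior_equilibria(inc):
        if eq.kind == "interior_minus":
            return eq
    return None


def _instability_preconditions(inc: IncentiveParams) -> tuple[bool, bool]:
    """The two incentive inequalities required for ``x_minus`` to be
    unstable: aggregate follower incentive positive, and follower product
    exceeding the leader product."""
    cond_sum = inc.deltaH1 + inc.dL0 > 0.0
    cond_prod = inc.deltaH1 * inc.dL0 > inc.deltaL1 * inc.dH0
    return cond_sum, cond_prod


def _max_re_at(inc: IncentiveParams, env: Environment, x_star: float, eps: float) -> float:
    sys = EcoEvoSystem(inc, env.with_epsilon(eps))
    eigs = np.linalg.eigvals(jacobian(sys, x_star, x_star))
    return float(np.max(eigs.real))


def epsilon_crit(
    inc: IncentiveParams,
    env: Environment,
    method: str = "bisection",
    search_range: tuple[float, float] = (1e-8, 1e4),
) -> Optional[float]:
    """Critical environmental timescale ratio for the Hopf bifurcation at
    ``x_minus``; the coexistence equilibrium is unstable (and a limit cycle
    possible) for ``epsilon`` below this value.

    Returns ``None`` when ``x_minus`` does not exist, when either incentive
    precondition for instability fails, or when the leading eigenvalue real
    part never changes sign over ``search_range``.

    ``method="bisection"`` (default) locates the sign change of the largest
    eigenvalue real part of the Jacobian at ``x_minus`` as a function of
    ``epsilon``.  ``method="trace"`` evaluates the trace-zero condition of
    the 2x2 Jacobian in closed form,
    ``eps_crit = x*(1-x) * dg/dx / B(x*)`` with ``B`` the environmental
    relaxation coefficient (``alpha`` for a decaying resource,
    ``r - q*(eL*x* + eH*(1-x*))`` for a renewing one); valid when the
    determinant at that epsilon is positive, and used as an independent
    cross-check of the bisection route.
    """
    _check_family(env)
    xm = _x_minus(inc)
    if xm is None:
        return None
    cond_sum, cond_prod = _instability_preconditions(inc)
    if not (cond_sum and cond_prod):
        return None
    x = xm.x_star

    if method == "trace":
        gx, _ = gain_gradient(x, x, inc)
        if isinstance(env, DecayingResource):
            b_coef = env.alpha
        else:
            b_coef = env.r - env.q * (env.eL * x + env.eH * (1.0 - x))
        eps = x * (1.0 - x) * gx / b_coef
        if eps <= 0.0:
            return None
        sys = EcoEvoSystem(inc, env.with_epsilon(eps))
        if np.linalg.det(jacobian(sys, x, x)) <= 0.0:
            return None
        return eps

    if method != "bisection":
        raise ValueError(f"unknown method {method!r}")

    lo, hi = search_range
    eps_grid = np.geomspace(lo, hi, 121)
    vals = [_max_re_at(inc, env, x, e) for e in eps_grid]
    bracket = None
    for i in range(len(eps_grid) - 1):
        if vals[i] == 0.0:
            return float(eps_grid[i])
        if vals[i] * vals[i + 1] < 0.0:
            bracket = (eps_grid[i], eps_grid[i + 1])
            break
    if bracket is None:
        return None
    root = brentq(lambda e: _max_re_at(inc, env, x, e), *bracket,
                  xtol=1e-14, rtol=1e-12)
    return float(root)


def _near(value: float, tol: float = DEGENERACY_TOL) -> bool:
    return abs(value) < tol


def classify_regime(
    inc: IncentiveParams,
    epsilon: float,
    env: Environment,
    probe_t_factor: float = 500.0,
    probe_rtol: float = 1e-9,
) -> RegimeReport:
    """Classify the global dynamical regime at timescale ratio ``epsilon``.

    The panel comes from the signs of the leading incentives ``deltaL1``
    and ``dH0``; within a panel the regime follows from edge stability,
    the interior equilibria, the two instability preconditions and
    ``epsilon`` versus ``epsilon_crit``:

    * panel a (both leading incentives negative): both edges stable, only
      the saddle inside -- ``bistable_edges``.
    * panel b (both positive): neither edge stable; ``stable_coexistence``
      or, when the follower incentives outweigh the leaders and the
      feedback is slow (``epsilon < epsilon_crit``), ``limit_cycle``.
    * panels c/d (mixed signs): one edge stable.  With no interior pair the
      stable edge dominates; with a stable ``x_minus`` the system is
      ``bistable_edge_interior``; with an unstable ``x_minus`` a bounded
      simulation probe around it distinguishes ``bistable_edge_cycle`` from
      dominance (very slow feedback destroys the cycle).

    Any defining inequality within ``1e-9`` of equality -- including a
    vanishing ``g`` on the nullcline -- yields ``boundary_degenerate``.
    """
    if epsilon <= 0.0:
        raise DomainError("epsilon must be positive")
    _check_family(env)
    env_at = env.with_epsilon(epsilon)
    sys = EcoEvoSystem(inc, env_at)

    conditions: dict = {
        "deltaL1": inc.deltaL1,
        "dH0": inc.dH0,
        "follower_sum_pos": inc.deltaH1 + inc.dL0 > 0.0,
        "follower_product_exceeds_leader": (
            inc.deltaH1 * inc.dL0 > inc.deltaL1 * inc.dH0
        ),
    }

    def report(panel: str, regime: str, eps_crit: Optional[float] = None) -> RegimeReport:
        return RegimeReport(panel=panel, regime=regime, epsilon=epsilon,
                            epsilon_crit=eps_crit, conditions=conditions)

    if _near(inc.deltaL1) or _near(inc.dH0):
        return report("-", "boundary_degenerate")

    panel = {(False, False): "a", (True, True): "b",
             (False, True): "c", (True, False): "d"}[
        (inc.deltaL1 > 0.0, inc.dH0 > 0.0)
    ]
    # note: deltaL1 < 0 keeps the rich edge (1,1) stable; dH0 < 0 keeps the
    # poor edge (0,0) stable
    if panel == "a":
        return report("a", "bistable_edges")

    # in the remaining panels the cycle decision hinges on the follower
    # inequalities; flag near-equalities there as degenerate
    if _near(inc.deltaH1 + inc.dL0) or _near(inc.deltaH1 * inc.dL0 - inc.deltaL1 * inc.dH0):
        return report(panel, "boundary_degenerate")

    try:
        interior = interior_equilibria(inc)
    except DegenerateSystemError:
        return report(panel, "boundary_degenerate")
    xm = next((e for e in interior if e.kind == "interior_minus"), None)

    eps_crit = epsilon_crit(inc, env)
    if eps_crit is not None and _near(epsilon - eps_crit):
        return report(panel, "boundary_degenerate", eps_crit)
    conditions["epsilon_below_crit"] = (
        eps_crit is not None and epsilon < eps_crit
    )

    if panel == "b":
        if xm is not None and conditions["epsilon_below_crit"]:
            return report("b", "limit_cycle", eps_crit)
        return report("b", "stable_coexistence", eps_crit)

    # panels c and d: one stable edge
    dominance = "dominance_L" if panel == "c" else "dominance_H"
    if xm is None:
        return report(panel, dominance, eps_crit)
    xm = classify_equilibrium(sys, xm)
    if xm.is_stable:
        return report(panel, "bistable_edge_interior", eps_crit)
    if xm.label == "nonhyperbolic":
        return report(panel, "boundary_degenerate", eps_crit)
    # unstable focus: cycle or dominance, resolved by a bounded simulation
    # probe around x_minus (deterministic given the configuration)
    if _probe_for_cycle(sys, xm, epsilon, probe_t_factor, probe_rtol):
        return report(panel, "bistable_edge_cycle", eps_crit)
    return report(panel, dominance, eps_crit)


_PROBE_OFFSETS = [(0.02, 0.02), (-0.02, -0.02), (0.02, -0.02),
                  (-0.02, 0.02), (0.04, 0.0)]


def _probe_for_cycle(sys: EcoEvoSystem, xm: Equilibrium, epsilon: float,
                     t_factor: float, rtol: float) -> bool:
    t_end = t_factor / epsilon
    for dx0, dn0 in _PROBE_OFFSETS:
        x0 = min(max(xm.x_star + dx0, 1e-3), 1.0 - 1e-3)
        n0 = min(max(xm.n_star + dn0, 1e-3), 1.0 - 1e-3)
        try:
            traj = integrate(sys, x0, n0, t_end, rtol=rtol, atol=rtol,
                             n_samples=8001)
        except Exception:
            continue
        diag = diagnose_attractor(traj)
        if diag.kind == "limit_cycle":
            return True
    return False


def equilibria_table(eqs: list[Equilibrium]) -> str:
    """TSV table of equilibria (kind, coordinates, eigenvalues, label)."""
    header = "kind\tx\tn\tre_eig1\tim_eig1\tre_eig2\tim_eig2\tlabel"
    lines = [header]
    for eq in eqs:
        e1, e2 = eq.eigenvalues if eq.eigenvalues is not None else (
            complex("nan"), complex("nan"))
        lines.append(
            f"{eq.kind}\t{eq.x_star:.12g}\t{eq.n_star:.12g}\t"
            f"{e1.real:.12g}\t{e1.imag:.12g}\t{e2.real:.12g}\t{e2.imag:.12g}\t"
            f"{eq.label}"
        )
    return "\n".join(lines) + "\n"
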