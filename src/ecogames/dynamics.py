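"""Coupled strategy-environment dynamics and numerical integration.

The state is ``(x, n)`` on the unit square: ``x`` is the frequency of the
low-impact strategy and ``n`` the normalised environmental state.  The
vector field is

    dx/dt = x * (1 - x) * g(x, n)        (replicator dynamics)
    dn/dt = environment drift            (see :mod:`ecogames.environments`)

where ``g = pi_L - pi_H`` is the bilinear gain.  Strategy-update speed is
normalised to one, so the environment's ``epsilon`` is the only timescale
ratio in the system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .environments import Environment
from .errors import DomainError, IntegrationError
from .games import IncentiveParams, _gain_unchecked

__all__ = ["EcoEvoSystem", "Trajectory", "vector_field", "integrate", "simulate_grid"]

#: trajectories may overshoot the unit square by at most this much before
#: clipping is considered to mask a solver fault
CLIP_TOL = 1e-8

#: early-exit threshold on the vector-field norm
CONVERGENCE_NORM = 1e-10


@dataclass(frozen=True)
class EcoEvoSystem:
    """An eco-evolutionary game: incentives plus an environment."""

    incentives: IncentiveParams
    environment: Environment

    def field(self, x, n):
        """Unchecked vector field; accepts arrays (used by solvers and
        vectorised sweeps)."""
        x = np.asarray(x, dtype=float)
        n = np.asarray(n, dtype=float)
        dx = x * (1.0 - x) * _gain_unchecked(x, n, self.incentives)
        dn = self.environment.drift(x, n)
        return dx, dn


@dataclass
class Trajectory:
    """A numerically integrated orbit of an eco-evolutionary system."""

    times: np.ndarray
    xs: np.ndarray
    ns: np.ndarray
    metadata: dict = field(default_factory=dict)
    system: Optional[EcoEvoSystem] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xs = np.asarray(self.xs, dtype=float)
        self.ns = np.asarray(self.ns, dtype=float)
        if not (len(self.times) == len(self.xs) == len(self.ns)):
            raise ValueError("times, xs, ns must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def terminal(self) -> tuple[float, float]:
        return float(self.xs[-1]), float(self.ns[-1])

    def tail(self, fraction: float) -> "Trajectory":
        """The final ``fraction`` of the trajectory (by time span)."""
        t0 = self.times[0] + (1.0 - fraction) * (self.times[-1] - self.times[0])
        i = int(np.searchsorted(self.times, t0))
        i = min(i, len(self.times) - 2) if len(self.times) > 1 else 0
        return Trajectory(self.times[i:], self.xs[i:], self.ns[i:],
                          dict(self.metadata), self.system)


def vector_field(sys: EcoEvoSystem, x: float, n: float) -> tuple[float, float]:
    """``(dx/dt, dn/dt)`` at a point of the unit square.

    Raises :class:`DomainError` outside ``[0, 1]^2``.
    """
    x = float(x)
    n = float(n)
    if not (0.0 <= x <= 1.0 and 0.0 <= n <= 1.0):
        raise DomainError(f"state ({x}, {n}) lies outside the unit square")
    dx, dn = sys.field(x, n)
    return float(dx), float(dn)


def _field_norm(sys: EcoEvoSystem, x: float, n: float) -> float:
    dx, dn = sys.field(min(max(x, 0.0), 1.0), min(max(n, 0.0), 1.0))
    return float(np.hypot(dx, dn))


def _logit(x: float) -> float:
    return float(np.log(x) - np.log1p(-x))


def _sigmoid(u):
    # numerically symmetric: never overflows, saturates to 0/1 in float
    u = np.asarray(u, dtype=float)
    out = np.where(u >= 0, 1.0 / (1.0 + np.exp(-np.abs(u))),
                   np.exp(-np.abs(u)) / (1.0 + np.exp(-np.abs(u))))
    return float(out) if out.ndim == 0 else out


def integrate(
    sys: EcoEvoSystem,
    x0: float,
    n0: float,
    t_end: float,
    rtol: float = 1e-9,
    atol: float = 1e-9,
    n_samples: int = 2001,
    method: str = "RK45",
) -> Trajectory:
    """Integrate the coupled dynamics from ``(x0, n0)`` over ``[0, t_end]``.

    The solution is sampled on a uniform time grid (``n_samples`` points up
    to the termination time) from the solver's dense output.  Integration
    stops early, with termination reason ``"converged"``, once the
    vector-field norm falls below ``1e-10`` -- a criterion on the field
    rather than on state differences, so crawling along a slow manifold
    near a saddle is not mistaken for convergence.

    States are clipped to the unit square after solving; any excursion
    beyond ``1e-8`` raises :class:`IntegrationError` (clipping must tidy
    round-off, not mask solver faults).
    """
    if not (0.0 <= x0 <= 1.0 and 0.0 <= n0 <= 1.0):
        raise DomainError(f"initial state ({x0}, {n0}) lies outside the unit square")
    if t_end <= 0:
        raise DomainError("t_end must be positive")
    if rtol <= 0 or atol <= 0:
        raise DomainError("tolerances must be positive")

    meta = {
        "solver": method, "rtol": rtol, "atol": atol,
        "x0": x0, "n0": n0, "t_end": t_end,
    }

    # Fixed-point start: nothing to solve.
    if _field_norm(sys, x0, n0) < CONVERGENCE_NORM:
        times = np.linspace(0.0, t_end, n_samples)
        meta["termination"] = "converged"
        return Trajectory(times, np.full_like(times, x0), np.full_like(times, n0),
                          meta, sys)

    on_x_edge = x0 in (0.0, 1.0)
    inc = sys.incentives

    if on_x_edge:
        # x-edges are exactly invariant; solve the environment alone.  The
        # drift polynomials extend smoothly beyond [0,1], so trial steps
        # slightly outside self-correct rather than being clipped flat.
        def rhs(t, y):
            return (float(sys.environment.drift(x0, y[0])),)

        def converged(t, y):
            return _field_norm(sys, x0, y[0]) - CONVERGENCE_NORM

        y_init = (float(n0),)
    else:
        # Interior starts are integrated in logit coordinates
        # u = log(x / (1 - x)):  du/dt = g(x, n) is bounded, so orbits that
        # approach the x-edges (relaxation cycles do, exponentially) are
        # tracked without collapsing onto the edge in floating point.
        def rhs(t, y):
            x = _sigmoid(y[0])
            du = float(_gain_unchecked(x, y[1], inc))
            dn = float(sys.environment.drift(x, y[1]))
            return (du, dn)

        def converged(t, y):
            return _field_norm(sys, _sigmoid(y[0]), y[1]) - CONVERGENCE_NORM

        y_init = (_logit(float(x0)), float(n0))

    converged.terminal = True
    converged.direction = -1

    sol = solve_ivp(
        rhs, (0.0, t_end), y_init,
        method=method, rtol=rtol, atol=atol,
        dense_output=True, events=converged,
    )

    def to_xn(ys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if on_x_edge:
            return np.full(ys.shape[1], x0), ys[0]
        return _sigmoid(ys[0]), ys[1]

    if not sol.success:
        partial = None
        if len(sol.t) > 1:
            xs, ns = to_xn(sol.y)
            meta["termination"] = "failure"
            partial = Trajectory(sol.t, xs, np.clip(ns, 0.0, 1.0), meta, sys)
        raise IntegrationError(f"ODE solver failed: {sol.message}", partial=partial)

    t_final = sol.t[-1]
    times = np.linspace(0.0, t_final, n_samples)
    xs, ns = to_xn(sol.sol(times))

    # At the default 1e-9 tolerances the contract is the strict 1e-8; at
    # looser tolerances the admissible excursion scales with the accuracy
    # actually requested.
    clip_tol = max(CLIP_TOL, 10.0 * max(rtol, atol))
    overshoot = max(0.0, float(np.max(ns - 1.0)), float(np.max(-ns)),
                    float(np.max(xs - 1.0)), float(np.max(-xs)))
    if overshoot > clip_tol:
        raise IntegrationError(
            f"trajectory left the unit square by {overshoot:.3e} (> {clip_tol:.0e})"
        )
    xs = np.clip(xs, 0.0, 1.0)
    ns = np.clip(ns, 0.0, 1.0)

    meta["termination"] = "converged" if sol.status == 1 else "t_end"
    meta["t_final"] = float(t_final)
    return Trajectory(times, xs, ns, meta, sys)


@dataclass(frozen=True)
class GridResult:
    """Outcome of one grid-point integration."""

    x0: float
    n0: float
    trajectory: Optional[Trajectory]
    error: Optional[str] = None


def simulate_grid(
    sys: EcoEvoSystem,
    grid_resolution: int,
    t_end: float,
    rtol: float = 1e-9,
    atol: float = 1e-9,
    n_samples: int = 2001,
) -> list[GridResult]:
    """Integrate from every interior point of a uniform lattice on the unit
    square (``grid_resolution`` points per axis, edges excluded).

    Per-point solver failures are recorded in the result rather than
    aborting the sweep.  Deterministic given the configuration.
    """
    if grid_resolution < 2:
        raise DomainError("grid_resolution must be at least 2")
    pts = np.linspace(0.0, 1.0, grid_resolution + 2)[1:-1]
    results: list[GridResult] = []
    for x0 in pts:
        for n0 in pts:
            try:
                traj = integrate(sys, float(x0), float(n0), t_end,
                                 rtol=rtol, atol=atol, n_samples=n_samples)
                results.append(GridResult(float(x0), float(n0), traj))
            except IntegrationError as exc:
                results.append(GridResult(float(x0), float(n0),
                                          exc.partial, error=str(exc)))
    return results
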