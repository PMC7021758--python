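"""Intrinsic environment classes and stock <-> state transforms.

Three families of environmental dynamics are supported, each normalised so
that the environmental state ``n`` lives on ``[0, 1]`` with ``n = 1`` the
state produced by a population of pure low-impact (L) strategists:

* :class:`RenewingResource` -- a logistically growing stock harvested at
  strategy-dependent effort; on the normalised state,
  ``dn/dt = eps * (r - q*(eL*n + eH*(1-n))) * (x - n)``.
* :class:`DecayingResource` -- a pollutant-like stock with first-order decay
  and strategy-dependent emissions; ``dn/dt = eps * alpha * (x - n)``.
  Note that for a pollutant, *high* stock means a *poor* environment, so the
  normalisation is orientation-reversing.
* Tipping-point environments -- a continuum of threshold units that flip
  state when the L-frequency crosses their individual tipping point,
  characterised by the threshold CDF ``F``:
  ``dn/dt = eps * n * (1 - n) * (x - F^{-1}(n))``.  The
  :class:`HeavisideTipping` variant is the zero-variance limit, which
  recovers the classic model of strategy-driven environmental switching
  with no intrinsic dynamics.

``eps`` (epsilon) is the speed of environmental change relative to strategy
updating; intrinsic and strategy-driven environmental timescales are taken
equal, so a single epsilon suffices per environment.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .errors import ConfigError, DomainError

__all__ = [
    "Environment",
    "RenewingResource",
    "DecayingResource",
    "ThresholdTipping",
    "UniformTipping",
    "HeavisideTipping",
    "env_drift",
    "stock_to_state",
    "state_to_stock",
    "weitz_limit_environment",
    "environment_from_dict",
    "environment_to_dict",
]


def _check_positive(name: str, value: float) -> float:
    value = float(value)
    if not (math.isfinite(value) and value > 0.0):
        raise DomainError(f"{name} must be a finite positive number, got {value!r}")
    return value


def _check_state(x, n) -> None:
    if np.any(np.asarray(x) < 0.0) or np.any(np.asarray(x) > 1.0):
        raise DomainError("strategy frequency x must lie in [0, 1]")
    if np.any(np.asarray(n) < 0.0) or np.any(np.asarray(n) > 1.0):
        raise DomainError("environmental state n must lie in [0, 1]")


class Environment:
    """Common interface of all environment classes."""

    epsilon: float

    def drift(self, x, n):
        """``dn/dt`` at ``(x, n)`` (no domain checks; see :func:`env_drift`)."""
        raise NotImplementedError

    def drift_gradient(self, x: float, n: float) -> tuple[float, float]:
        """Exact partials ``(d(dn/dt)/dx, d(dn/dt)/dn)``."""
        raise NotImplementedError

    def with_epsilon(self, epsilon: float) -> "Environment":
        """A copy of this environment with a different timescale ratio."""
        return dataclasses.replace(self, epsilon=_check_positive("epsilon", epsilon))


@dataclass(frozen=True)
class RenewingResource(Environment):
    """Logistic resource stock under strategy-dependent harvest.

    Parameters
    ----------
    r : intrinsic growth rate (1/time)
    k : carrying capacity (stock units)
    q : catchability, maps effort into per-stock removal rate (1/(effort*time))
    eL, eH : harvest efforts of the L and H strategies, with
        ``0 <= eL < eH < r/q`` so the stock is positive at both monomorphic
        equilibria
    epsilon : environmental speed relative to strategy updating
    """

    r: float
    k: float
    q: float
    eL: float
    eH: float
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        _check_positive("r", self.r)
        _check_positive("k", self.k)
        _check_positive("q", self.q)
        _check_positive("epsilon", self.epsilon)
        if not (0.0 <= self.eL < self.eH):
            raise DomainError(
                f"efforts must satisfy 0 <= eL < eH, got eL={self.eL}, eH={self.eH}"
            )
        if not self.eH < self.r / self.q:
            raise DomainError(
                f"eH must be below r/q={self.r / self.q} for a positive stock, "
                f"got eH={self.eH}"
            )

    def _bracket(self, n):
        # r - q*(eL*n + eH*(1-n)); positive on [0,1] under the effort bounds
        return self.r - self.q * (self.eL * np.asarray(n) + self.eH * (1.0 - np.asarray(n)))

    def drift(self, x, n):
        return self.epsilon * self._bracket(n) * (np.asarray(x) - np.asarray(n))

    def drift_gradient(self, x: float, n: float) -> tuple[float, float]:
        b = float(self._bracket(n))
        db = self.q * (self.eH - self.eL)
        return self.epsilon * b, self.epsilon * (db * (x - n) - b)

    # -- raw stock space -------------------------------------------------
    @property
    def stock_L(self) -> float:
        """Steady-state stock under pure L harvest: ``k*(1 - q*eL/r)``."""
        return self.k * (1.0 - self.q * self.eL / self.r)

    @property
    def stock_H(self) -> float:
        """Steady-state stock under pure H harvest: ``k*(1 - q*eH/r)``."""
        return self.k * (1.0 - self.q * self.eH / self.r)

    def stock_rate(self, m, x):
        """Raw stock dynamics ``dm/dt`` (logistic growth minus harvest),
        on the environmental timescale.  Retained as a verification oracle
        for the normalised drift."""
        m = np.asarray(m, dtype=float)
        harvest = self.q * m * (self.eL * x + self.eH * (1.0 - x))
        return self.epsilon * (self.r * m * (1.0 - m / self.k) - harvest)


@dataclass(frozen=True)
class DecayingResource(Environment):
    """First-order decaying stock (e.g. a pollutant) with strategy-dependent
    emissions.  ``eL < eH`` are the emission rates of the low- and
    high-emission strategies; they only matter for raw-stock transforms --
    the normalised drift ``eps*alpha*(x - n)`` depends on ``alpha`` alone."""

    alpha: float
    eL: Optional[float] = None
    eH: Optional[float] = None
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        _check_positive("alpha", self.alpha)
        _check_positive("epsilon", self.epsilon)
        if (self.eL is None) != (self.eH is None):
            raise DomainError("provide both eL and eH, or neither")
        if self.eL is not None:
            if not (0.0 <= self.eL < self.eH):
                raise DomainError(
                    f"emissions must satisfy 0 <= eL < eH, got eL={self.eL}, eH={self.eH}"
                )

    def drift(self, x, n):
        return self.epsilon * self.alpha * (np.asarray(x) - np.asarray(n))

    def drift_gradient(self, x: float, n: float) -> tuple[float, float]:
        return self.epsilon * self.alpha, -self.epsilon * self.alpha

    @property
    def stock_L(self) -> float:
        """Steady-state pollutant level under pure L emissions: ``eL/alpha``."""
        self._need_emissions()
        return self.eL / self.alpha

    @property
    def stock_H(self) -> float:
        self._need_emissions()
        return self.eH / self.alpha

    def stock_rate(self, m, x):
        """Raw pollutant dynamics ``dm/dt = -alpha*m + eL*x + eH*(1-x)``,
        on the environmental timescale (verification oracle)."""
        self._need_emissions()
        m = np.asarray(m, dtype=float)
        return self.epsilon * (-self.alpha * m + self.eL * x + self.eH * (1.0 - x))

    def _need_emissions(self) -> None:
        if self.eL is None:
            raise DomainError("raw-stock transforms need emission rates eL, eH")


@dataclass(frozen=True)
class ThresholdTipping(Environment):
    """Tipping-point environment with an arbitrary strictly increasing
    threshold CDF, supplied through its inverse ``F_inv`` on (0, 1).

    ``F_inv_prime`` (derivative of the inverse CDF) is optional; when absent
    the Jacobian falls back to a central finite difference.  Threshold
    support may exceed [0, 1]; ``F_inv(n)`` is used as-is and the drift
    remains well defined.
    """

    F_inv: Callable[[float], float]
    epsilon: float = 1.0
    F_inv_prime: Optional[Callable[[float], float]] = None

    def __post_init__(self) -> None:
        _check_positive("epsilon", self.epsilon)

    def drift(self, x, n):
        n_arr = np.asarray(n, dtype=float)
        finv = np.vectorize(self.F_inv)(n_arr) if n_arr.ndim else self.F_inv(float(n_arr))
        return self.epsilon * n_arr * (1.0 - n_arr) * (np.asarray(x) - finv)

    def drift_gradient(self, x: float, n: float) -> tuple[float, float]:
        dn_dx = self.epsilon * n * (1.0 - n)
        if self.F_inv_prime is not None:
            fp = self.F_inv_prime(n)
        else:
            h = 1e-6
            lo, hi = max(n - h, 1e-12), min(n + h, 1.0 - 1e-12)
            fp = (self.F_inv(hi) - self.F_inv(lo)) / (hi - lo)
        dn_dn = self.epsilon * (
            (1.0 - 2.0 * n) * (x - self.F_inv(n)) - n * (1.0 - n) * fp
        )
        return dn_dx, dn_dn


@dataclass(frozen=True)
class UniformTipping(Environment):
    """Tipping thresholds uniform on ``[mu - a/2, mu + a/2]``.

    ``F_inv(n) = mu - a/2 + a*n``, so the drift reduces to the closed form
    ``eps * n * (1-n) * (x - a*n + a/2 - mu)``.
    """

    mu: float
    a: float
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        _check_positive("a", self.a)
        _check_positive("epsilon", self.epsilon)
        if not math.isfinite(self.mu):
            raise DomainError("mu must be finite")

    def F_inv(self, n: float) -> float:
        return self.mu - self.a / 2.0 + self.a * n

    def drift(self, x, n):
        n_arr = np.asarray(n, dtype=float)
        return (
            self.epsilon
            * n_arr
            * (1.0 - n_arr)
            * (np.asarray(x) - self.a * n_arr + self.a / 2.0 - self.mu)
        )

    def drift_gradient(self, x: float, n: float) -> tuple[float, float]:
        dn_dx = self.epsilon * n * (1.0 - n)
        dn_dn = self.epsilon * (
            (1.0 - 2.0 * n) * (x - self.a * n + self.a / 2.0 - self.mu)
            - n * (1.0 - n) * self.a
        )
        return dn_dx, dn_dn


@dataclass(frozen=True)
class HeavisideTipping(Environment):
    """Zero-variance tipping environment: every unit shares the threshold
    ``mu = 1/(1+theta)``.

    Implemented as the limiting drift
    ``eps_tilde * n * (1-n) * (theta*x - (1-x))`` with
    ``eps_tilde = epsilon / (1 + theta)`` -- algebraically identical to
    ``epsilon * n * (1-n) * (x - mu)`` -- rather than by inverting the
    degenerate step CDF.  This is the classic model in which the
    environment has no intrinsic dynamics and is enhanced by one strategy
    (rate ``theta``) and degraded by the other (rate 1).
    """

    theta: float
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        _check_positive("theta", self.theta)
        _check_positive("epsilon", self.epsilon)

    @property
    def mu(self) -> float:
        return 1.0 / (1.0 + self.theta)

    @property
    def eps_tilde(self) -> float:
        return self.epsilon / (1.0 + self.theta)

    def drift(self, x, n):
        n_arr = np.asarray(n, dtype=float)
        x_arr = np.asarray(x, dtype=float)
        return (
            self.eps_tilde
            * n_arr
            * (1.0 - n_arr)
            * (self.theta * x_arr - (1.0 - x_arr))
        )

    def drift_gradient(self, x: float, n: float) -> tuple[float, float]:
        dn_dx = self.epsilon * n * (1.0 - n)
        dn_dn = self.epsilon * (1.0 - 2.0 * n) * (x - self.mu)
        return dn_dx, dn_dn


def env_drift(env: Environment, x, n):
    """``dn/dt`` with domain validation; scalar in, scalar out."""
    _check_state(x, n)
    value = env.drift(x, n)
    arr = np.asarray(value)
    return float(arr) if arr.ndim == 0 else arr


def stock_to_state(env: Environment, m):
    """Map a raw stock level ``m`` to the normalised state ``n``.

    The affine map sends the pure-H steady-state stock to ``n = 0`` and the
    pure-L steady-state stock to ``n = 1``; for a decaying (pollutant)
    resource this reverses orientation, since low pollutant means a rich
    environment.
    """
    mL, mH = _steady_stocks(env)
    m = np.asarray(m, dtype=float)
    out = (m - mH) / (mL - mH)
    return float(out) if out.ndim == 0 else out


def state_to_stock(env: Environment, n):
    """Inverse of :func:`stock_to_state`."""
    mL, mH = _steady_stocks(env)
    n = np.asarray(n, dtype=float)
    out = mH + n * (mL - mH)
    return float(out) if out.ndim == 0 else out


def _steady_stocks(env: Environment) -> tuple[float, float]:
    if not isinstance(env, (RenewingResource, DecayingResource)):
        raise DomainError("stock transforms apply to renewing/decaying resources only")
    mL, mH = env.stock_L, env.stock_H
    if math.isclose(mL, mH):
        raise DomainError("eL == eH gives a degenerate stock-to-state transform")
    return mL, mH


def weitz_limit_environment(theta: float, eps_tilde: float) -> HeavisideTipping:
    """The zero-variance tipping environment equivalent to strategy-driven
    switching at enhancement rate ``theta`` and speed ``eps_tilde``.

    Places the common tipping point at ``mu = 1/(1+theta)`` and rescales the
    timescale to ``epsilon = (1+theta) * eps_tilde``.
    """
    _check_positive("theta", theta)
    _check_positive("eps_tilde", eps_tilde)
    return HeavisideTipping(theta=float(theta), epsilon=(1.0 + float(theta)) * float(eps_tilde))


# -- JSON config blocks --------------------------------------------------

def environment_from_dict(block: dict) -> Environment:
    """Build an environment from a JSON config block, e.g.
    ``{"type": "renewing", "r": 1, "k": 1, "q": 1, "eL": 0.1, "eH": 0.5,
    "epsilon": 0.1}`` or ``{"type": "tipping", "dist": "uniform",
    "mu": 0.5, "a": 0.1, "epsilon": 1}``."""
    if not isinstance(block, dict) or "type" not in block:
        raise ConfigError("environment block must be an object with a 'type' key")
    kind = block["type"]
    try:
        if kind == "renewing":
            return RenewingResource(
                r=block["r"], k=block["k"], q=block["q"],
                eL=block["eL"], eH=block["eH"],
                epsilon=block.get("epsilon", 1.0),
            )
        if kind == "decaying":
            return DecayingResource(
                alpha=block["alpha"],
                eL=block.get("eL"), eH=block.get("eH"),
                epsilon=block.get("epsilon", 1.0),
            )
        if kind == "tipping":
            dist = block.get("dist", "uniform")
            if dist == "uniform":
                return UniformTipping(
                    mu=block["mu"], a=block["a"], epsilon=block.get("epsilon", 1.0)
                )
            if dist == "heaviside":
                return HeavisideTipping(
                    theta=block["theta"], epsilon=block.get("epsilon", 1.0)
                )
            raise ConfigError(f"unknown tipping distribution {dist!r}")
    except KeyError as exc:
        raise ConfigError(f"environment block missing key {exc.args[0]!r}") from exc
    except DomainError as exc:
        raise ConfigError(f"invalid environment parameters: {exc}") from exc
    raise ConfigError(f"unknown environment type {kind!r}")


def environment_to_dict(env: Environment) -> dict:
    if isinstance(env, RenewingResource):
        return {"type": "renewing", "r": env.r, "k": env.k, "q": env.q,
                "eL": env.eL, "eH": env.eH, "epsilon": env.epsilon}
    if isinstance(env, DecayingResource):
        out = {"type": "decaying", "alpha": env.alpha, "epsilon": env.epsilon}
        if env.eL is not None:
            out.update(eL=env.eL, eH=env.eH)
        return out
    if isinstance(env, UniformTipping):
        return {"type": "tipping", "dist": "uniform", "mu": env.mu, "a": env.a,
                "epsilon": env.epsilon}
    if isinstance(env, HeavisideTipping):
        return {"type": "tipping", "dist": "heaviside", "theta": env.theta,
                "epsilon": env.epsilon}
    raise ConfigError(f"cannot serialise environment of type {type(env).__name__}")
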