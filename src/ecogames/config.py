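"""Run configurations: JSON schema, validation, hashing.

A run config is a JSON object with

* exactly one of ``"incentives"`` (object with ``deltaL1``, ``deltaH1``,
  ``dL0``, ``dH0``) or ``"payoffs"`` (object with ``R0``..``P1``);
* an ``"environment"`` block (see
  :func:`ecogames.environments.environment_from_dict`); ``"epsilon"`` may
  be given at top level and overrides the block's value;
* either ``"initial"`` (``{"x0": .., "n0": ..}``) for single runs or
  ``"grid"`` for sweeps;
* optional ``"t_end"``, ``"rtol"``, ``"atol"``, ``"seed"``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Optional

from .dynamics import EcoEvoSystem
from .environments import Environment, environment_from_dict
from .errors import ConfigError, DomainError
from .games import IncentiveParams, PayoffStructure, incentives_from_payoffs

__all__ = ["RunConfig", "load_config", "parse_config", "config_hash"]

_INCENTIVE_KEYS = {"deltaL1", "deltaH1", "dL0", "dH0"}
_PAYOFF_KEYS = {"R0", "S0", "T0", "P0", "R1", "S1", "T1", "P1"}


@dataclass
class RunConfig:
    incentives: IncentiveParams
    environment: Environment
    x0: Optional[float] = None
    n0: Optional[float] = None
    grid: Optional[dict] = None
    t_end: float = 100.0
    rtol: float = 1e-9
    atol: float = 1e-9
    seed: int = 0
    raw: Optional[dict] = None

    @property
    def system(self) -> EcoEvoSystem:
        return EcoEvoSystem(self.incentives, self.environment)

    @property
    def hash(self) -> str:
        return config_hash(self.raw or {})


def config_hash(obj: dict) -> str:
    """Stable short hash of a config object (key-sorted canonical JSON)."""
    canon = json.dumps(obj, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def parse_config(obj: dict) -> RunConfig:
    """Validate and build a :class:`RunConfig` from a decoded JSON object."""
    if not isinstance(obj, dict):
        raise ConfigError("config root must be a JSON object")

    has_inc = "incentives" in obj
    has_pay = "payoffs" in obj
    if has_inc == has_pay:
        raise ConfigError("config must contain exactly one of 'incentives' or 'payoffs'")
    try:
        if has_inc:
            block = obj["incentives"]
            _require_keys("incentives", block, _INCENTIVE_KEYS)
            incentives = IncentiveParams(**{k: block[k] for k in _INCENTIVE_KEYS})
        else:
            block = obj["payoffs"]
            _require_keys("payoffs", block, _PAYOFF_KEYS)
            incentives = incentives_from_payoffs(
                PayoffStructure(**{k: block[k] for k in _PAYOFF_KEYS})
            )
    except DomainError as exc:
        raise ConfigError(str(exc)) from exc

    if "environment" not in obj:
        raise ConfigError("config missing 'environment' block")
    env = environment_from_dict(obj["environment"])
    if "epsilon" in obj:
        try:
            env = env.with_epsilon(obj["epsilon"])
        except DomainError as exc:
            raise ConfigError(str(exc)) from exc

    cfg = RunConfig(incentives=incentives, environment=env, raw=obj)
    if "initial" in obj:
        init = obj["initial"]
        _require_keys("initial", init, {"x0", "n0"})
        cfg.x0, cfg.n0 = float(init["x0"]), float(init["n0"])
        if not (0.0 <= cfg.x0 <= 1.0 and 0.0 <= cfg.n0 <= 1.0):
            raise ConfigError("initial state must lie in the unit square")
    if "grid" in obj:
        cfg.grid = obj["grid"]
    for key, cast in (("t_end", float), ("rtol", float), ("atol", float), ("seed", int)):
        if key in obj:
            setattr(cfg, key, cast(obj[key]))
    if cfg.t_end <= 0 or cfg.rtol <= 0 or cfg.atol <= 0:
        raise ConfigError("t_end and tolerances must be positive")
    return cfg


def load_config(path: str) -> RunConfig:
    """Read and validate a JSON config file.

    Malformed JSON raises :class:`ConfigError` carrying the line/column of
    the syntax error.
    """
    with open(path) as fh:
        text = fh.read()
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConfigError(
            f"{path}: malformed JSON at line {exc.lineno}, column {exc.colno}: {exc.msg}"
        ) from exc
    return parse_config(obj)


def _require_keys(name: str, block, keys: set[str]) -> None:
    if not isinstance(block, dict):
        raise ConfigError(f"'{name}' must be a JSON object")
    missing = keys - block.keys()
    if missing:
        raise ConfigError(f"'{name}' missing keys: {sorted(missing)}")
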