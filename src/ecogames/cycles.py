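"""Long-run attractor diagnosis: fixed points, limit cycles, basins.

Cycle detection works on the peak sequence of ``x(t)``: local maxima are
located from sign changes of ``dx/dt`` (evaluated exactly from the vector
field, not by differencing), which stays robust when cycles hug the edges
of the unit square.  A trajectory is called a limit cycle when the last few
peaks have settled -- peak heights and inter-peak intervals drifting by
less than 1% -- at a peak-to-trough amplitude above a floor that separates
genuine cycles from slowly damped foci near the Hopf point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dynamics import EcoEvoSystem, Trajectory, integrate, simulate_grid
from .errors import DomainError
from .games import _gain_unchecked

__all__ = ["AttractorDiagnosis", "BasinEstimate", "diagnose_attractor", "estimate_basins"]

#: peak-to-trough amplitudes below this are not called cycles
AMPLITUDE_FLOOR = 1e-3

_CORNERS = [(0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0)]


@dataclass
class AttractorDiagnosis:
    """Classification of a trajectory's long-run behaviour."""

    kind: str  # fixed_point | limit_cycle | edge_state | undetermined
    location: Optional[tuple[float, float]] = None  # fixed point, or cycle mean
    amplitude: Optional[float] = None  # peak-to-trough in x
    period: Optional[float] = None
    notes: list[str] = field(default_factory=list)


def _peaks_and_troughs(traj: Trajectory) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Times and interpolated values of local maxima of x(t), plus trough
    values, from sign changes of dx/dt along the sample grid."""
    sys = traj.system
    t, x, n = traj.times, traj.xs, traj.ns
    if sys is not None:
        # sign of dx/dt = sign of the gain for interior x; using the gain
        # keeps the sign meaningful even where x has rounded onto an edge
        dx = _gain_unchecked(x, n, sys.incentives)
    else:
        dx = np.gradient(x, t)
    sign = np.sign(dx)
    # + -> - crossing: local maximum between samples i and i+1
    up_down = np.where((sign[:-1] > 0) & (sign[1:] <= 0))[0]
    down_up = np.where((sign[:-1] < 0) & (sign[1:] >= 0))[0]

    def refine(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        times, values = [], []
        for i in idx:
            # linear crossing time of dx, parabolic value through neighbours
            d0, d1 = dx[i], dx[i + 1]
            frac = d0 / (d0 - d1) if d0 != d1 else 0.5
            tc = t[i] + frac * (t[i + 1] - t[i])
            j = max(1, min(i if frac < 0.5 else i + 1, len(t) - 2))
            coeffs = np.polyfit(t[j - 1: j + 2] - tc, x[j - 1: j + 2], 2)
            times.append(tc)
            values.append(np.polyval(coeffs, 0.0))
        return np.asarray(times), np.asarray(values)

    peak_t, peak_x = refine(up_down)
    _, trough_x = refine(down_up)
    return peak_t, peak_x, trough_x


def diagnose_attractor(
    traj: Trajectory,
    transient_fraction: float = 0.5,
    amplitude_floor: float = AMPLITUDE_FLOOR,
    max_extensions: int = 3,
) -> AttractorDiagnosis:
    """Classify the attractor a trajectory has settled onto.

    The first ``transient_fraction`` of the time span is discarded.  The
    terminal state decides the easy cases: within ``1e-6`` of a corner is
    an ``edge_state``; vector-field norm below ``1e-8`` is a
    ``fixed_point``.  Otherwise the post-transient peak sequence of ``x``
    is examined: at least four settled peaks (heights and spacings drifting
    < 1% over the last three periods) with amplitude above the floor is a
    ``limit_cycle``.  Anything else is ``undetermined`` with an explanatory
    note; when the trajectory carries its system and simply ran out of
    time, it is extended (doubling the span, at most ``max_extensions``
    times) before giving up.
    """
    if not 0.0 <= transient_fraction < 1.0:
        raise DomainError("transient_fraction must lie in [0, 1)")

    for attempt in range(max_extensions + 1):
        diag = _diagnose_once(traj, transient_fraction, amplitude_floor)
        if diag.kind != "undetermined":
            return diag
        sys = traj.system
        if sys is None or attempt == max_extensions:
            return diag
        # extend: continue from the terminal state for twice the span
        span = traj.times[-1] - traj.times[0]
        x1, n1 = traj.terminal
        meta = traj.metadata
        cont = integrate(
            sys, x1, n1, 2.0 * max(span, 1.0),
            rtol=meta.get("rtol", 1e-9), atol=meta.get("atol", 1e-9),
            n_samples=max(len(traj.times), 4001),
        )
        traj = Trajectory(
            np.concatenate([traj.times, traj.times[-1] + cont.times[1:]]),
            np.concatenate([traj.xs, cont.xs[1:]]),
            np.concatenate([traj.ns, cont.ns[1:]]),
            cont.metadata, sys,
        )
    return diag  # pragma: no cover


def _diagnose_once(traj: Trajectory, transient_fraction: float,
                   amplitude_floor: float) -> AttractorDiagnosis:
    if len(traj.times) < 8:
        return AttractorDiagnosis("undetermined",
                                  notes=["trajectory too short to classify"])
    xT, nT = traj.terminal
    for cx, cn in _CORNERS:
        # corners are exact equilibria; snap near-corner terminals onto them
        if abs(xT - cx) < 1e-6 and abs(nT - cn) < 1e-6:
            xT, nT = cx, cn
            break
    if traj.system is not None:
        dx, dn = traj.system.field(xT, nT)
        if float(np.hypot(float(dx), float(dn))) < 1e-8:
            return AttractorDiagnosis("fixed_point", location=(xT, nT))
    for cx, cn in _CORNERS:
        # near a corner but not yet settled: still relaxing along an edge
        if abs(xT - cx) < 1e-6 and abs(nT - cn) < 1e-6:
            return AttractorDiagnosis("edge_state", location=(cx, cn))

    tail = traj.tail(1.0 - transient_fraction)
    peak_t, peak_x, trough_x = _peaks_and_troughs(tail)
    if len(peak_t) < 4 or len(trough_x) < 3:
        return AttractorDiagnosis(
            "undetermined",
            notes=[f"only {len(peak_t)} post-transient peaks; need >= 4"],
        )

    periods = np.diff(peak_t[-4:])
    last_peaks = peak_x[-3:]
    last_troughs = trough_x[-3:]
    amplitude = float(np.mean(last_peaks) - np.mean(last_troughs))
    period = float(np.mean(periods))

    peak_drift = float(np.ptp(last_peaks)) / max(amplitude, 1e-300)
    period_drift = float(np.ptp(periods)) / max(period, 1e-300)
    if amplitude > amplitude_floor and peak_drift < 0.01 and period_drift < 0.01:
        mean_loc = (float(np.mean(tail.xs)), float(np.mean(tail.ns)))
        return AttractorDiagnosis(
            "limit_cycle", location=mean_loc,
            amplitude=amplitude, period=period,
            notes=[f"{len(peak_t)} settled peaks"],
        )
    if amplitude <= amplitude_floor:
        note = f"oscillation amplitude {amplitude:.2e} below floor {amplitude_floor:.0e}"
    else:
        note = (f"peaks not settled (height drift {peak_drift:.2%}, "
                f"period drift {period_drift:.2%})")
    return AttractorDiagnosis("undetermined", amplitude=amplitude,
                              period=period, notes=[note])


@dataclass
class BasinEstimate:
    """Grid-based basin-of-attraction estimate."""

    xs: np.ndarray  # grid coordinates per axis
    labels: np.ndarray  # (res, res) int array; -1 = undetermined/error
    attractors: list[AttractorDiagnosis]  # inventory, indexed by label
    diagnoses: list[AttractorDiagnosis]  # one per cell, row-major
    undetermined: int = 0


def _attractor_key(diag: AttractorDiagnosis) -> Optional[tuple]:
    if diag.kind in ("fixed_point", "edge_state"):
        x, n = diag.location
        for cx, cn in _CORNERS:
            # corner fixed points and still-relaxing edge states share an
            # identity for basin purposes
            if abs(x - cx) < 1e-3 and abs(n - cn) < 1e-3:
                return ("corner", cx, cn)
        return ("fixed_point", round(x, 2), round(n, 2))
    if diag.kind == "limit_cycle":
        return ("limit_cycle",)  # one cycle class per system in practice
    return None


def estimate_basins(
    sys: EcoEvoSystem,
    grid_resolution: int,
    t_end: float,
    rtol: float = 1e-8,
    n_samples: int = 4001,
    transient_fraction: float = 0.5,
) -> BasinEstimate:
    """Label each interior grid cell by the attractor it reaches.

    Runs :func:`ecogames.dynamics.simulate_grid` and diagnoses every cell;
    cells whose diagnosis stays undetermined are reported (label ``-1``),
    not dropped.  Deterministic given the configuration.
    """
    if grid_resolution < 10:
        raise DomainError("grid_resolution must be at least 10 for basin estimates")
    results = simulate_grid(sys, grid_resolution, t_end,
                            rtol=rtol, atol=rtol, n_samples=n_samples)
    pts = np.linspace(0.0, 1.0, grid_resolution + 2)[1:-1]
    labels = np.full((grid_resolution, grid_resolution), -1, dtype=int)
    inventory: dict[tuple, int] = {}
    attractors: list[AttractorDiagnosis] = []
    diagnoses: list[AttractorDiagnosis] = []
    undetermined = 0

    for idx, res in enumerate(results):
        i, j = divmod(idx, grid_resolution)
        if res.trajectory is None:
            diag = AttractorDiagnosis("undetermined", notes=[res.error or "no trajectory"])
        else:
            diag = diagnose_attractor(res.trajectory, transient_fraction,
                                      max_extensions=1)
        diagnoses.append(diag)
        key = _attractor_key(diag)
        if key is None:
            undetermined += 1
            continue
        if key not in inventory:
            inventory[key] = len(attractors)
            attractors.append(diag)
        labels[i, j] = inventory[key]

    return BasinEstimate(xs=pts, labels=labels, attractors=attractors,
                         diagnoses=diagnoses, undetermined=undetermined)
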