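import numpy as np
import pytest

from ecogames import (
    DecayingResource,
    DomainError,
    EcoEvoSystem,
    IncentiveParams,
    RenewingResource,
    UniformTipping,
    gain,
    integrate,
    simulate_grid,
    vector_field,
)

from conftest import random_incentives


def test_corners_are_fixed_points(cycling_system):
    sys = cycling_system(0.1)
    assert vector_field(sys, 0.0, 0.0) == (0.0, 0.0)
    assert vector_field(sys, 1.0, 1.0) == (0.0, 0.0)


def test_strategy_edges_have_zero_strategy_flow(cycling_system, rng):
    sys = cycling_system(0.1)
    for n in rng.uniform(0, 1, 20):
        assert vector_field(sys, 0.0, n)[0] == 0.0
        assert vector_field(sys, 1.0, n)[0] == 0.0


def test_vector_field_reference_point(cycling_incentives):
    """At the centre of the square the strategy flow is x(1-x)*g with g
    evaluated by the independent corner-interpolation formula, and the
    environmental flow vanishes on the nullcline."""
    inc = cycling_incentives
    sys = EcoEvoSystem(inc, DecayingResource(alpha=1.0, epsilon=0.1))
    g_corner = 0.25 * (inc.dH0 + inc.dL0 - inc.deltaH1 - inc.deltaL1)
    dx, dn = vector_field(sys, 0.5, 0.5)
    assert dx == pytest.approx(0.25 * g_corner)
    assert dn == 0.0


def test_vector_field_domain_error(cycling_system):
    with pytest.raises(DomainError):
        vector_field(cycling_system(0.1), 1.2, 0.5)


def test_fixed_point_start_yields_constant_trajectory(cycling_system):
    traj = integrate(cycling_system(0.1), 0.0, 0.0, 10.0)
    assert np.all(traj.xs == 0.0) and np.all(traj.ns == 0.0)
    assert traj.metadata["termination"] == "converged"


def test_edge_trajectory_stays_on_edge_and_n_relaxes(cycling_system):
    traj = integrate(cycling_system(0.5), 1.0, 0.2, 60.0)
    assert np.all(traj.xs == 1.0)
    # monotone approach to n=1 (up to dense-output interpolation jitter)
    assert np.all(np.diff(traj.ns) >= -1e-8)
    assert traj.ns[-1] == pytest.approx(1.0, abs=1e-6)


def test_tipping_n_edges_invariant(cycling_incentives):
    env = UniformTipping(mu=0.5, a=0.4, epsilon=1.0)
    sys = EcoEvoSystem(cycling_incentives, env)
    for n0 in (0.0, 1.0):
        traj = integrate(sys, 0.3, n0, 20.0)
        assert np.all(traj.ns == n0)


def test_trajectories_contained_in_unit_square(rng):
    """Seeded random systems and starts: no state ever leaves [0,1]^2 by
    more than solver tolerance (clipping would have raised otherwise)."""
    for _ in range(40):
        inc = random_incentives(rng)
        env_kind = rng.integers(3)
        if env_kind == 0:
            env = DecayingResource(alpha=float(rng.uniform(0.5, 2)),
                                   epsilon=float(rng.uniform(0.05, 2)))
        elif env_kind == 1:
            env = RenewingResource(r=1.0, k=1.0, q=1.0, eL=0.1, eH=0.5,
                                   epsilon=float(rng.uniform(0.05, 2)))
        else:
            env = UniformTipping(mu=float(rng.uniform(0.2, 0.8)),
                                 a=float(rng.uniform(0.1, 1.0)),
                                 epsilon=float(rng.uniform(0.05, 2)))
        x0, n0 = rng.uniform(0, 1, 2)
        traj = integrate(EcoEvoSystem(inc, env), float(x0), float(n0), 30.0,
                         rtol=1e-8, atol=1e-8, n_samples=501)
        assert np.all((traj.xs >= 0) & (traj.xs <= 1))
        assert np.all((traj.ns >= 0) & (traj.ns <= 1))


def test_time_rescaling_leaves_orbit_unchanged(cycling_incentives):
    """Scaling both the gain and epsilon by c reparameterises time without
    moving the orbit: state at time t in the scaled system equals state at
    time c*t in the original."""
    c = 3.0
    env = DecayingResource(alpha=1.0, epsilon=0.2)
    sys1 = EcoEvoSystem(cycling_incentives, env)
    inc_scaled = IncentiveParams(
        *(c * v for v in (cycling_incentives.deltaL1, cycling_incentives.deltaH1,
                          cycling_incentives.dL0, cycling_incentives.dH0))
    )
    sys2 = EcoEvoSystem(inc_scaled, env.with_epsilon(0.2 * c))
    t_end = 30.0
    tr1 = integrate(sys1, 0.8, 0.3, t_end, n_samples=301)
    tr2 = integrate(sys2, 0.8, 0.3, t_end / c, n_samples=301)
    assert np.allclose(tr1.xs, tr2.xs, atol=1e-6)
    assert np.allclose(tr1.ns, tr2.ns, atol=1e-6)


def test_integrate_validates_inputs(cycling_system):
    sys = cycling_system(0.1)
    with pytest.raises(DomainError):
        integrate(sys, 1.5, 0.5, 10.0)
    with pytest.raises(DomainError):
        integrate(sys, 0.5, 0.5, -1.0)
    with pytest.raises(DomainError):
        integrate(sys, 0.5, 0.5, 10.0, rtol=-1e-9)


def test_bistable_grid_splits_between_corners(panel_a_incentives, decaying):
    """With both leading incentives negative every interior start is
    absorbed by one of the two monomorphic corners."""
    # resolution chosen so no lattice point sits on the saddle's stable
    # manifold x = 1/2 (starts there legitimately converge to the saddle)
    sys = EcoEvoSystem(panel_a_incentives, decaying)
    results = simulate_grid(sys, 4, 200.0, rtol=1e-8, atol=1e-8, n_samples=201)
    assert len(results) == 16
    seen = set()
    for res in results:
        x1, n1 = res.trajectory.terminal
        corner = (round(x1), round(n1))
        assert abs(x1 - corner[0]) < 1e-4 and abs(n1 - corner[1]) < 1e-4
        seen.add(corner)
    assert seen == {(0, 0), (1, 1)}


def test_zero_incentives_grid_relaxes_to_nullcline(decaying):
    """With g identically zero, x never moves and n relaxes onto n = x."""
    sys = EcoEvoSystem(IncentiveParams(0, 0, 0, 0), decaying)
    results = simulate_grid(sys, 4, 80.0, rtol=1e-8, atol=1e-8, n_samples=101)
    for res in results:
        x1, n1 = res.trajectory.terminal
        assert x1 == pytest.approx(res.x0, abs=1e-9)
        assert n1 == pytest.approx(res.x0, abs=1e-5)


def test_simulate_grid_deterministic(cycling_system):
    sys = cycling_system(0.3)
    r1 = simulate_grid(sys, 3, 20.0, n_samples=101)
    r2 = simulate_grid(sys, 3, 20.0, n_samples=101)
    for a, b in zip(r1, r2):
        assert np.array_equal(a.trajectory.xs, b.trajectory.xs)
        assert np.array_equal(a.trajectory.ns, b.trajectory.ns)
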