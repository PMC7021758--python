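import numpy as np
import pytest

from ecogames import (
    DecayingResource,
    DegenerateSystemError,
    DomainError,
    EcoEvoSystem,
    IncentiveParams,
    UniformTipping,
    all_equilibria,
    classify_equilibrium,
    classify_regime,
    epsilon_crit,
    interior_equilibria,
    jacobian,
)
from ecogames.equilibria import Equilibrium, nullcline_quadratic

from conftest import random_incentives


def sign_scan_roots(inc, step=1e-6):
    """Independent root oracle: dense sign scan of g(x, x) on (0, 1)."""
    a, b, c = nullcline_quadratic(inc)
    x = np.arange(step, 1.0, step)
    q = (a * x + b) * x + c
    idx = np.where(np.sign(q[:-1]) * np.sign(q[1:]) < 0)[0]
    return [0.5 * (x[i] + x[i + 1]) for i in idx]


def test_interior_roots_match_sign_scan(cycling_incentives, mixed_incentives):
    for inc, expected in [
        (cycling_incentives, [1.0 / np.sqrt(3.0)]),
        (mixed_incentives, [0.40698272, 0.95887094]),
    ]:
        roots = sorted(e.x_star for e in interior_equilibria(inc))
        scan = sign_scan_roots(inc)
        assert len(roots) == len(scan)
        assert roots == pytest.approx(scan, abs=1e-6)
        assert roots == pytest.approx(expected, abs=1e-6)
        for e in interior_equilibria(inc):
            assert e.n_star == e.x_star


def test_no_interior_root_when_gain_keeps_one_sign():
    # dH0 < 0, deltaL1 > 0, followers zero: q(x) = dH0*(1-x)^2 - deltaL1*x^2
    # is negative on all of (0, 1), so no coexistence point exists
    inc = IncentiveParams(deltaL1=1.0, deltaH1=0.0, dL0=0.0, dH0=-1.0)
    assert interior_equilibria(inc) == []
    assert sign_scan_roots(inc) == []


def test_identically_zero_gain_is_a_continuum():
    with pytest.raises(DegenerateSystemError):
        interior_equilibria(IncentiveParams(0, 0, 0, 0))


def test_all_equilibria_counts(cycling_incentives, mixed_incentives, decaying, rng):
    env = decaying
    assert len(all_equilibria(EcoEvoSystem(cycling_incentives, env))) == 3
    assert len(all_equilibria(EcoEvoSystem(mixed_incentives, env))) == 4
    for _ in range(100):
        inc = random_incentives(rng)
        try:
            eqs = all_equilibria(EcoEvoSystem(inc, env))
        except DegenerateSystemError:
            continue
        assert len(eqs) in (2, 3, 4)
        kinds = [e.kind for e in eqs]
        assert kinds.count("edge_poor") == 1 and kinds.count("edge_rich") == 1


def test_equilibria_restricted_to_intrinsic_environments(cycling_incentives):
    sys = EcoEvoSystem(cycling_incentives, UniformTipping(mu=0.5, a=0.3))
    with pytest.raises(DomainError):
        all_equilibria(sys)


def fd_jacobian(sys, x, n, h=1e-6):
    """Central finite differences of the vector field (clipped stencil)."""
    out = np.empty((2, 2))
    for col in range(2):
        lo = [x, n]
        hi = [x, n]
        lo[col] = max(lo[col] - h, 0.0)
        hi[col] = min(hi[col] + h, 1.0)
        flo = sys.field(lo[0], lo[1])
        fhi = sys.field(hi[0], hi[1])
        denom = hi[col] - lo[col]
        out[0, col] = (float(fhi[0]) - float(flo[0])) / denom
        out[1, col] = (float(fhi[1]) - float(flo[1])) / denom
    return out


def test_jacobian_matches_finite_differences(cycling_incentives, mixed_incentives,
                                             decaying, renewing, rng):
    systems = [
        EcoEvoSystem(cycling_incentives, decaying.with_epsilon(0.3)),
        EcoEvoSystem(mixed_incentives, renewing.with_epsilon(0.7)),
        EcoEvoSystem(cycling_incentives, UniformTipping(mu=0.5, a=0.4, epsilon=0.5)),
    ]
    for sys in systems:
        for _ in range(25):
            x, n = rng.uniform(0.05, 0.95, 2)
            jac = jacobian(sys, float(x), float(n))
            ref = fd_jacobian(sys, float(x), float(n))
            assert np.allclose(jac, ref, rtol=1e-5, atol=1e-5)


def test_jacobian_closed_form_at_poor_corner(decaying):
    inc = IncentiveParams(deltaL1=2.0, deltaH1=1.0, dL0=3.0, dH0=-1.5)
    eps, alpha = 0.4, 1.0
    sys = EcoEvoSystem(inc, decaying.with_epsilon(eps))
    jac = jacobian(sys, 0.0, 0.0)
    assert np.allclose(jac, [[inc.dH0, 0.0], [eps * alpha, -eps * alpha]])


def test_zero_incentives_strategy_row_vanishes(decaying):
    sys = EcoEvoSystem(IncentiveParams(0, 0, 0, 0), decaying)
    assert np.allclose(jacobian(sys, 0.5, 0.5)[0], 0.0)


def test_edge_stability_follows_leading_incentives(decaying, rng):
    """(0,0) is stable exactly when dH0 < 0 and (1,1) exactly when
    deltaL1 < 0 (generic nonzero incentives)."""
    for _ in range(200):
        inc = random_incentives(rng)
        sys = EcoEvoSystem(inc, decaying)
        poor = classify_equilibrium(sys, Equilibrium(0.0, 0.0, "edge_poor"))
        rich = classify_equilibrium(sys, Equilibrium(1.0, 1.0, "edge_rich"))
        assert poor.is_stable == (inc.dH0 < 0)
        assert rich.is_stable == (inc.deltaL1 < 0)


def test_classification_examples(cycling_incentives, mixed_incentives, decaying):
    sys3 = EcoEvoSystem(cycling_incentives, decaying)
    rich = classify_equilibrium(sys3, Equilibrium(1.0, 1.0, "edge_rich"))
    # deltaL1 = 2 > 0: repelling along the strategy direction (here the
    # environment direction still contracts, so the corner is a saddle)
    assert not rich.is_stable
    sys4 = EcoEvoSystem(mixed_incentives, decaying)
    saddle = [e for e in all_equilibria(sys4) if e.kind == "interior_plus"]
    assert len(saddle) == 1 and saddle[0].label == "saddle"


def test_classify_rejects_non_fixed_point(cycling_incentives, decaying):
    sys = EcoEvoSystem(cycling_incentives, decaying)
    with pytest.raises(DomainError):
        classify_equilibrium(sys, Equilibrium(0.3, 0.7, "edge_poor"))


def test_epsilon_crit_two_methods_agree(cycling_incentives, mixed_incentives,
                                        decaying, renewing):
    for inc in (cycling_incentives, mixed_incentives):
        for env in (decaying, renewing):
            e_bis = epsilon_crit(inc, env)
            e_tr = epsilon_crit(inc, env, method="trace")
            assert e_bis is not None and e_tr is not None
            assert abs(e_bis - e_tr) / e_tr < 1e-6


def test_epsilon_crit_reference_value(cycling_incentives, decaying):
    # x* = 1/sqrt(3), dg/dx on the nullcline = 2 - 3x*, alpha = 1
    x = 1.0 / np.sqrt(3.0)
    expected = x * (1.0 - x) * (2.0 - 3.0 * x)
    e = epsilon_crit(cycling_incentives, decaying)
    assert e == pytest.approx(expected, rel=1e-9)
    assert e == pytest.approx(0.0654, abs=2e-4)


def test_epsilon_crit_none_when_preconditions_fail(decaying):
    # equal lead/follow incentives: on the cycle boundary, no Hopf
    assert epsilon_crit(IncentiveParams(1, 1, 1, 1), decaying) is None
    # follower sum negative
    assert epsilon_crit(IncentiveParams(2, -3, 1, 1), decaying) is None
    # follower product below leader product
    assert epsilon_crit(IncentiveParams(3, 1, 1, 2), decaying) is None


def test_hopf_eigenvalue_crossing(cycling_incentives, decaying):
    """Just below epsilon_crit the coexistence point is an unstable focus,
    just above it a stable focus."""
    ec = epsilon_crit(cycling_incentives, decaying)
    xm = interior_equilibria(cycling_incentives)[0]
    for factor, stable in ((0.9, False), (1.1, True)):
        sys = EcoEvoSystem(cycling_incentives, decaying.with_epsilon(factor * ec))
        eq = classify_equilibrium(sys, Equilibrium(xm.x_star, xm.n_star, xm.kind))
        assert eq.is_stable == stable
        assert eq.label.endswith("focus")


def test_regime_panel_a(decaying):
    rep = classify_regime(IncentiveParams(-1, 1, 1, -1), 0.5, decaying)
    assert rep.panel == "a" and rep.regime == "bistable_edges"


def test_regime_cycling_epsilon_dichotomy(cycling_incentives, decaying):
    low = classify_regime(cycling_incentives, 0.02, decaying)
    high = classify_regime(cycling_incentives, 0.2, decaying)
    assert (low.panel, low.regime) == ("b", "limit_cycle")
    assert (high.panel, high.regime) == ("b", "stable_coexistence")
    assert low.epsilon_crit == pytest.approx(0.0654, abs=2e-4)


def test_regime_mixed_panel_ladder(mixed_incentives, decaying):
    assert classify_regime(mixed_incentives, 0.35, decaying).regime == "bistable_edge_interior"
    assert classify_regime(mixed_incentives, 0.25, decaying).regime == "bistable_edge_cycle"
    assert classify_regime(mixed_incentives, 0.05, decaying).regime == "dominance_L"


def test_regime_degenerate_boundary(decaying):
    rep = classify_regime(IncentiveParams(1, 1, 1, 1), 0.5, decaying)
    assert rep.regime == "boundary_degenerate"


def test_renewing_decaying_concordance(cycling_incentives, mixed_incentives,
                                       panel_a_incentives, decaying, renewing):
    """Matched incentives give the same qualitative regime for both
    intrinsic environment families (at epsilon well away from both
    families' Hopf thresholds)."""
    cases = [
        (panel_a_incentives, 0.5),
        (cycling_incentives, 1.0),   # well above both epsilon_crit values
        (cycling_incentives, 0.01),  # well below both
        (mixed_incentives, 1.0),
    ]
    for inc, eps in cases:
        r_dec = classify_regime(inc, eps, decaying)
        r_ren = classify_regime(inc, eps, renewing)
        assert r_dec.regime == r_ren.regime


def test_equilibrium_set_matches_newton_sweep(decaying, rng):
    """Oracle: damped Newton iteration from a 30x30 grid of starts finds
    exactly the analytically enumerated fixed points (100 seeded draws,
    degenerate draws skipped)."""
    from test_acceptance import newton_fixed_point_xs, nondegenerate

    checked = 0
    for _ in range(100):
        inc = random_incentives(rng)
        roots = nondegenerate(inc)
        if roots is None:
            continue
        analytic = sorted([0.0, 1.0] + roots)
        numeric = newton_fixed_point_xs(inc, res=30)
        assert len(numeric) == len(analytic)
        assert numeric == pytest.approx(analytic, abs=1e-6)
        checked += 1
    assert checked >= 80
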