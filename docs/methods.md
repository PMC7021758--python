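# Methods

## Model

`ecogames` studies two-strategy games whose payoffs depend on an
environmental state that the strategies themselves drive. The state is
`(x, n) ∈ [0,1]²`: `x` is the frequency of the low-impact strategy L and
`n` the normalised environmental state (`n = 1` rich, `n = 0` poor).
Strategy frequencies follow replicator dynamics and the environment relaxes
toward the state the current strategy mix produces:

    dx/dt = x (1 − x) g(x, n),        g = π_L − π_H
    dn/dt = ε · D(x, n)

The payoff matrix is linear in `n`, `Π(n) = (1−n) Π₀ + n Π₁`, so the gain
`g` is bilinear and fully determined by four incentive parameters — the
corner values of `g`:

| parameter | corner | interpretation |
|---|---|---|
| `deltaL1 = T1 − R1` | `−g(1,1)` | lead a gold rush (switch to H first, rich env) |
| `deltaH1 = P1 − S1` | `−g(0,1)` | follow a gold rush |
| `dL0 = R0 − T0` | `g(1,0)` | follow an environmental movement |
| `dH0 = S0 − P0` | `g(0,0)` | lead an environmental movement (switch to L first, poor env) |

Strategy-update speed is normalised to one; `ε` is the speed of
environmental change relative to strategy updating, and the intrinsic and
strategy-driven environmental timescales are taken equal, so a single `ε`
remains.

Three environment families supply `D`:

* **Renewing** — a logistic stock harvested at strategy-dependent effort;
  on the normalised state `D = (r − q(e_L n + e_H (1−n)))(x − n)`. The
  effort bounds `0 ≤ e_L < e_H < r/q` keep the bracket positive on [0,1].
* **Decaying** — a pollutant with first-order decay, `D = α (x − n)`
  (orientation-reversed: low pollutant is the rich state).
* **Tipping** — a continuum of threshold units with CDF `F`,
  `D = n(1−n)(x − F⁻¹(n))`. The zero-variance (Heaviside) limit has no
  intrinsic dynamics and reproduces strategy-driven environmental switching
  with enhancement rate θ, via `μ = 1/(1+θ)` and `ε = (1+θ) ε̃`; it is
  implemented as the limiting drift `ε̃ n(1−n)(θx − (1−x))` rather than by
  inverting the degenerate step CDF.

The raw-stock forms of the renewing and decaying models are kept only as
verification oracles (`stock_rate`, `stock_to_state`): differentiating the
affine stock↔state transform along the raw dynamics reproduces the
normalised drift exactly, and a test asserts this to integration tolerance.
Generic threshold CDFs whose support exceeds [0,1] are allowed; `F⁻¹(n)` is
used as-is.

## Equilibria and stability

For renewing/decaying environments `sign(dn/dt) = sign(x − n)`, so all
fixed points lie on the nullcline `n = x`: the two monomorphic corners plus
the roots in (0,1) of the quadratic `q(x) = g(x,x)`. Up to four equilibria
exist. Interior kinds are assigned by the saddle property — the Jacobian
determinant at an interior point has the opposite sign of `q'(x)`, so the
root with `q'(x) > 0` is the saddle `x₊` and the other is `x₋`. If `q`
vanishes identically the fixed-point set is a continuum and a
`DegenerateSystemError` is raised rather than returning an empty list.

The Jacobian is closed-form (the gain is bilinear, the drifts polynomial).
Labels follow the eigenvalues: negative determinant is a saddle, otherwise
the sign of the largest real part decides stability, with node/focus split
by complexity; real parts or determinants within 1e-9 of zero are reported
`nonhyperbolic`. The edge-stability conditions are biconditional for
generic parameters: `(0,0)` is stable iff
`dH0 < 0` and `(1,1)` iff `deltaL1 < 0`; corners with a positive outgoing
strategy eigenvalue and the always-contracting environment eigenvalue are
topological saddles and labelled as such.

`x₋` loses stability in a Hopf bifurcation as `ε` decreases: the Jacobian
trace at `x₋` is `x(1−x) g_x − ε B(x)` with `B` the environmental
relaxation coefficient, so slow feedback destabilises coexistence.
`epsilon_crit` is computed two independent ways that a test requires to
agree to 1e-6 relative: (i) a Brent root-solve of the largest eigenvalue
real part over `ε ∈ (1e-8, 1e4)` (primary), and (ii) the trace-zero closed
form `ε_crit = x₋(1−x₋) g_x(x₋,x₋)/B(x₋)`, accepted only where the
determinant at that `ε` is positive. Instability additionally requires
`deltaH1 + dL0 > 0` and `deltaH1·dL0 > deltaL1·dH0`; when either fails, or
no sign change exists, `None` is returned (no Hopf threshold).

## Regime classification

The signs of the two leading incentives pick the panel: both negative →
bistable edges; both positive → neither edge stable, giving stable
coexistence or (when the follower inequalities hold and `ε < ε_crit`) a
limit cycle; mixed signs → one stable edge, with dominance, bistability
with a stable interior point, or bistability with a cycle. In the mixed
panels the cycle-versus-dominance decision below `ε_crit` has no closed
form in this package: a bounded deterministic simulation probe (five fixed
starts offset ~0.02 from `x₋`, horizon `500/ε`) diagnoses whether a cycle
surrounds the unstable focus. Numerically, the cycle in the mixed-panel
reference system (deltaL1=−1/8, deltaH1=4, dL0=1, dH0=2, α=1) exists for
`ε` between ≈0.2405 and ε_crit ≈ 0.2621 and is destroyed below that window
in a homoclinic collision with the saddle — hence the probe ladder
0.35/0.25/0.05 used in tests spans stable interior → bistable cycle →
dominance. Any decision-relevant inequality within 1e-9 of equality yields
`boundary_degenerate` rather than a forced label.

## Numerical integration

Interior trajectories are integrated in logit coordinates for the strategy
variable: `u = log(x/(1−x))`, `du/dt = g(σ(u), n)` is bounded and smooth.
This matters because relaxation cycles approach the strategy edges within
`~e^{-c/ε}`; in direct coordinates `x` underflows onto the edge and the
orbit is spuriously absorbed at a corner, destroying exactly the cycles of
interest. Starts on a strategy edge (exactly invariant) integrate the
environment alone. The right-hand side never clips: gain and drift are
polynomials that extend smoothly outside the unit square, so trial-step
excursions self-correct. After solving, states are clipped to [0,1]; an
excursion beyond 1e-8 (scaled up as `10·max(rtol, atol)` when looser
tolerances are requested) raises an error instead of being masked.

Defaults: RK45 with `rtol = atol = 1e-9` (cycle amplitudes near the Hopf
point are tolerance-sensitive; a test checks amplitude and period move by
<1% when tolerances are halved), dense output sampled on a uniform grid
(2001 points unless asked otherwise). Integration stops early once the
vector-field norm falls below 1e-10 — a criterion on the field, not on
state differences, so crawling along a slow manifold near a saddle is not
misreported as convergence; in logit coordinates the norm only reaches that
level inside a genuine equilibrium's basin.

## Attractor diagnosis

The first half of a trajectory is discarded as transient (configurable).
Terminal states within 1e-6 of a corner snap onto it; a terminal
vector-field norm below 1e-8 is a fixed point; a near-corner terminal that
is still drifting is an `edge_state`. Otherwise the peak sequence of `x(t)`
is examined: local maxima are located from sign changes of the *gain*
(identical in sign to dx/dt for interior x, but still meaningful where
stored x has rounded onto an edge), with parabolic refinement of peak times
and heights. A limit cycle requires at least four post-transient peaks
whose heights and spacings drift by less than 1% over the last three
periods, at a peak-to-trough amplitude above 1e-3 — the floor that
separates genuine cycles from slowly damped foci near the Hopf point.
Anything else is `undetermined` with an explanatory note; when the
trajectory carries its system and simply ran out of time it is extended
from its terminal state (doubling the span, at most three times) before
giving up. Basin estimation integrates every interior point of a uniform
lattice and groups diagnoses by attractor identity (corner, rounded
interior fixed point, or cycle); undetermined cells are reported, never
dropped.

## Case studies

The common-pool harvesting model maps the linear profit
`π(e, η) = (p q η − w) e` on a logistic stock onto the framework:
`deltaL1 = deltaH1 = (p q η_L − w)(e_H − e_L)` and
`dL0 = dH0 = (w − p q η_H)(e_H − e_L)` with `η_L, η_H` the monomorphic
equilibrium stocks. Lead and follow incentives coincide, pinning the model
exactly onto the boundary `deltaH1·dL0 = deltaL1·dH0` of the
cycle-permitting region: no positive `ε` produces cycles, and under the
textbook profit signs (positive at `η_L`, negative at `η_H`) the only
outcome is stable coexistence, which `common_pool_outcome` returns
directly; other sign cases delegate to the general classifier. A payoff-
matrix construction route exists alongside the direct formulas and a test
requires the two to agree to machine precision. The grass–legume case
ships as an ordering predicate over user-supplied incentives (all four
positive, `deltaL1 < deltaH1`, `dH0 < dL0`), not a mechanistic nitrogen
model — the ecological argument is by signs and orderings only, and those
orderings imply the follower product dominates, hence a positive Hopf
threshold.

## What the tests do and do not show

Test problem sizes: 2000-draw structural sweeps and 500-draw oracle sweeps
with incentives uniform on [−5, 5]⁴ against a decaying environment with
`α = ε = 1`; a vectorised damped-Newton detector from a 50×50 grid of
starts is the independent fixed-point oracle, and finite-difference
Jacobians the independent stability oracle. Cycle and basin tests use the
two reference parameterisations above with horizons up to a few thousand
time units and 10×10 basin lattices. Draws within 1e-3 of a root tangency
or an edge are excluded from grid-oracle comparisons, which cannot resolve
them.

Known limitations: the mixed-panel sub-region boundaries are resolved by
the simulation probe, not closed form; the zero-variance tipping limit is
probed by simulation only (no heteroclinic-cycle analysis); nonlinear
payoff extensions (market pricing, frequency-dependent efficiency) and
more than two strategies are out of scope; the generic threshold-CDF
environment ships without a reference non-uniform parameterisation. All
dynamics are deterministic planar ODEs — nothing here speaks to finite
populations, noise, or spatial structure.
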