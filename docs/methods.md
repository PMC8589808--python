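# Methods

## Model

The package integrates the CTRNN `dy_i/dt = -y_i + Σ_j w_ij φ(y_j) + I_i(t)`
on `N` cells, with either the logistic activation `φ_S` or the continuous
piecewise-affine activation `φ_P` (zero below `θ - 2ε`, one above `θ + 2ε`,
slope `1/(4ε)` between). The stochastic variant adds independent additive
white noise `σ dW_i(t)` to every cell. For the smooth activation the
firing-rate change of coordinates `J_i = φ(y_i)` gives
`dJ_i/dt = (1/ε) J_i (1-J_i)(-φ⁻¹(J_i) + Σ_j w_ij J_j)` on the open cube
`(0,1)^N`; it is implemented input-free only (the transformation is derived
for the autonomous system) and is used as a consistency check against the
`y`-form, not as the primary integrator.

## Construction and its guarantees

Admissibility (no one-loops, two-loops or Δ-cliques) is exactly what makes
the role assignment at each designed equilibrium well defined: at `ξ_k` every
cell is Active, Leading, Trailing or Disconnected, with levels `Y_A = w_s`,
`Y_L = w_p`, `Y_T = w_m`, `Y_D = w_t`. Under the recipe (`ε = δ/8`, `θ = ½`,
`w_s = 1`, `w_t = 0`, `w_p = θ - δ/2`, `w_m = -(w_s-θ) - δ/2`) and piecewise
activation, every component of `ξ_k` lies strictly farther than `2ε` from
`θ`, so each `φ_P` factor is exactly 0 or 1, the residual is exactly zero in
floating point, and the Jacobian is `-I`. The test suite asserts these
identities exactly, not to a tolerance.

During a transition `k → l` the remaining cells fall into six bystander
classes (DD, TD, LD, TL, DT, DL) determined by the four adjacency entries
`(a_jk, a_kj, a_jl, a_lj)`; patterns outside the table are impossible for
admissible graphs and raise an internal-consistency error.

## Numerical verification of realisation

`test_connection` starts at the Newton-refined `ξ_k`, applies the kick
`ξ_k + δ e_l`, and integrates the input-free system in 5-time-unit chunks
until the state stays within `δ/4` (max-norm) of one candidate equilibrium
for a full chunk. Candidates are the `N` refined vertex states plus the
all-off state near the origin, which is a genuine attractor and must not be
mistaken for a vertex. The dwell requirement (5 units at radius `δ/4`)
reflects the scale separation of the construction: equilibria are `O(θ)`
apart, transits are `O(1)` on the unit relaxation time, and the default
horizon is 200 units. Reaching `ξ_l` is `connected`, `ξ_k` is `returned`,
anything else `other`; a realisation report is the conjunction over all
ordered pairs.

Newton refinement uses the analytic Jacobian `-I + W diag(φ')`, 50 iteration
cap, and accepts residuals below `1e-10` (max-norm). Non-convergence is the
*detection mechanism* for post-fold regimes — but it is not sufficient on
its own: past the fold, Newton from the stale guess frequently converges to
a *different* equilibrium (the reversed state or the all-off state). All
existence tests therefore additionally require stability and max-norm
proximity (< 0.2, comfortably below the `O(θ)` spacing of distinct states)
to the designed level pattern.

## Bifurcation thresholds

* `wp_sn_closed_form` evaluates the asymptotic two-cell fold
  `w_p^SN = ε ln ε + θ - ε(1 + ln w_s) + ε²/w_s`, truncated at `ε²`.
* `wp_sn_numeric` solves the extended system {two-cell field = 0,
  det(Jacobian) = 0} in `(y_1, y_2, w_p)` with a hybrid Newton seeded from
  the nullcline-extremum asymptotics (`x_± = ½ ± sqrt(¼ - ε/w_s)`), falling
  back to existence bisection. Agreement with the closed form is `O(ε³)`
  (measured constant ≈ 1.0–1.3 over ε ∈ {0.05, 0.025, 0.0125}).
* `snic_threshold_cycle` bisects `w_p` on existence of the stable one-active
  equilibrium of the three-cell cycle (bracket `[θ-0.2, θ+0.1]`, absolute
  tolerance `1e-6`). By symmetry the three folds coincide, and the
  equilibrium-existence boundary is precisely the SNIC point; periodic-orbit
  continuation is deliberately out of scope. At the default parameters this
  yields `0.302879`, within `1e-5` of the two-cell fold.
* `wp_sn_prime` treats a vertex with two leading cells: on the sheet where
  the active cell is saturated the pair `(J_3, J_4)` obeys
  `g(J_3) = w_p + Δw + w_t J_4`, `g(J_4) = w_p + w_t J_3` with
  `g(x) = φ⁻¹(x) - w_s x`. The fold is located by continuing the solution
  branch connected to the stable decoupled pair upward in `w_p` (Newton in
  logit coordinates, so the iteration cannot leave the domain) and bisecting
  where the branch disappears. At `w_t = 0` the equations decouple and the
  threshold is `g(x_-) - max(Δw, 0)` exactly. Note the sheet idealisation
  (`J_active = 1`) differs from the full two-cell fold by the exponentially
  small saturation gap `~exp((θ-w_s)/ε)` (≈ 3e-5 at ε = 0.05); consistency
  tests between the two use a 5e-5 tolerance for this reason. Solving the
  coupled pair in closed form would require a quartic whose roots are not
  illuminating; we do not attempt it.

## Itineraries and activity statistics

A cell is *active* when its rate `φ(y)` is high; since "high" has no sharp
definition we use hysteresis (on at 0.8, off at 0.2) to prevent chatter
during fast transitions. Two time scales matter downstream:

* **Handover overlap.** During an ordinary transition the outgoing and
  incoming Active cells — always an *edge* pair — briefly overlap above
  threshold for `O(1)` time units (measured ≈ 0.8–1.3 at the default
  parameters). This is not a network state.
* **Double-activation states.** Two sibling leading cells igniting together
  (the `P_{3,4}` phenomenon at a branching vertex) form a pair with *no*
  edge between them, and persist on the dwell scale of states. The
  discriminator used throughout is therefore structural: a multi-activation
  event is a dwell-filtered active set containing a non-adjacent pair. This
  cleanly separates suppression (`w_t = -0.3`: zero such events across all
  tested seeds) from the permissive regime (`w_t = 0`: `{3,4}` entered
  repeatedly), where duration thresholds alone cannot.

Transition statistics count dwell-filtered (≥ 1 time unit) entries into
named target sets, optionally restricted to a source set; walk execution
uses a 5-unit dwell filter because its states persist for the full
inter-pulse settle time (30 units) while overlaps stay `O(1)`.

## Integrators

Deterministic runs use adaptive RK45 (`rtol = atol = 1e-9`) with output
sampled at spacing ≤ 0.1; `φ_P` is continuous and the field Lipschitz, so no
event detection is needed at the corners. The time axis is split at pulse
edges so rectangular inputs never straddle an integrator step. Stochastic
runs use fixed-step Euler–Maruyama (`dt = 0.01`), one seeded Gaussian
increment per cell per step; additive noise makes this adequate for the
qualitative transition statistics reported, and `σ = 0` reproduces the
deterministic Euler path bitwise. Noise path discretisation finer than
`dt = 0.01` changes transition counts only within seed-to-seed variability,
so statistics are treated as qualitative throughout.

## Random admissible graphs

Plain rejection sampling (each ordered pair independent with probability
`p`, violations discarded, budget 10,000 attempts) reproduces the natural
conditional distribution and is used by default. Requiring strong
connectivity ("no feed-forward structure", read as: every vertex revisitable)
cannot be layered onto plain rejection: at densities compatible with
admissibility, essentially no sample is strongly connected (0 of 2161
admissible `n = 10, p = 0.15` samples in a calibration run), since some
vertex almost surely lacks an outgoing or incoming edge. With the
connectivity flag, each attempt is therefore seeded with a uniformly random
Hamiltonian cycle — itself admissible and strongly connected — before the
independent pairs are added, and admissibility of the combined graph is
still enforced by rejection. The shipped ten-node fixture was generated this
way (`p = 0.15`, seed 2023) and has the qualitative features that matter:
several vertices with two outgoing edges, so both branching and suppression
phenomena are exercised.

## Problem sizes and defaults

Default study conditions follow the recipe at `δ = 0.4` (hence `ε = 0.05`,
`w_p = 0.3`, `w_m = -0.7`), noise `σ = 0.05` for the four-node branching
network (with `σ = 0.01` for the ten-node runs), horizons of 500 time units
for stochastic itineraries and ≤ 1200 for deterministic period measurements,
10 seeds per stochastic property, and 50 random graphs of 3–8 vertices for
the realisation property. These sizes give every reported effect a
comfortable margin (e.g. the suppression contrast is 26 events vs 0) while
keeping the full suite around half a minute.

## What the tests do and do not show

The verification is numerical, not proof-grade: basins are probed only along
the specific kicks `ξ_k + δ e_l`, so near-complete realisation (almost every
small perturbation either stays or follows an encoded edge) is sampled
evidence, not certified. Periodicity in the all-spontaneous regime is
asserted only on the tested fixtures. The noisy runs emulate isotropic
additive noise; real systems with state-dependent or correlated noise, or
heterogeneous activation functions across cells, are outside what passing
tests demonstrate. Mixed excitable/spontaneous outgoing connections are
exercised only implicitly (per-edge `w_p` draws in the ten-node runs);
no quantitative contract is offered there. Fold thresholds assume
`θ < w_s` and `w_s > 4ε`; outside those hypotheses the functions warn or
refuse rather than extrapolate.
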