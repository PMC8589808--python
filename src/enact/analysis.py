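"""Verification and bifurcation analysis of constructed excitable networks.

This module answers the questions that certify a construction numerically:

* does a Newton-refined stable equilibrium exist for each vertex, and does a
  ``delta``-kick along each graph edge (and only along graph edges) carry the
  state to the corresponding neighbour equilibrium (realisation verification);
* where in ``w_p`` does the one-active-cell equilibrium fold and disappear
  (saddle-node, SNIC and double-activation thresholds);
* what symbolic itinerary -- a time-stamped sequence of active-cell sets --
  does a given trajectory spell out, and what are its transition statistics.

The scalar map ``g(x) = phi^{-1}(x) - w_s x`` organises the fold computations:
its local maximum at ``x_- = 1/2 - sqrt(1/4 - eps/w_s)`` is where the slow
nullcline folds, and ``g(x_-)`` is the leading-order fold value of ``w_p``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, root
from scipy.special import expit, logit

from .construct import (
    ActivationSpec,
    ConstructionParams,
    Equilibrium,
    WeightMatrix,
    activation,
    activation_derivative,
    activation_inverse,
    build_weight_matrix,
    predicted_equilibrium,
)
from .dynamics import PulseSpec, Trajectory, kick, simulate_ode
from .graphs import DiGraph

__all__ = [
    "NoEquilibriumError",
    "InvalidWalkError",
    "TransitionOutcome",
    "RealisationReport",
    "Itinerary",
    "BifurcationResult",
    "refine_equilibrium",
    "equilibrium_candidates",
    "test_connection",
    "verify_realisation",
    "itinerary",
    "dwell_filtered_events",
    "estimate_period",
    "wp_sn_closed_form",
    "wp_sn_numeric",
    "snic_threshold_cycle",
    "wp_sn_prime",
    "lemma2_positions",
    "detect_bottlenecks",
    "transition_statistics",
    "execute_walk",
]


class NoEquilibriumError(RuntimeError):
    """Newton refinement did not converge.

    This is informative rather than fatal: past a fold the sought equilibrium
    no longer exists, and this error is the detection mechanism.
    """


class InvalidWalkError(ValueError):
    """A requested walk contains a pair that is not a graph edge."""


# ---------------------------------------------------------------------------
# Equilibrium refinement


def refine_equilibrium(
    W: WeightMatrix,
    spec: ActivationSpec,
    guess: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-12,
) -> Equilibrium:
    """Newton-refine a fixed point of the input-free field from ``guess``.

    Returns the point with its Jacobian eigenvalues and stability flag.  For
    the piecewise activation at a recipe equilibrium the guess is already an
    exact fixed point (all components saturated, Jacobian ``-I``) and is
    returned unchanged.  Raises :class:`NoEquilibriumError` on
    non-convergence, which downstream code uses to detect post-fold regimes.
    """
    y = np.asarray(guess, dtype=float).copy()
    if not np.all(np.isfinite(y)):
        raise ValueError("guess must be finite")
    for _ in range(max_iter):
        f = -y + W.w @ activation(y, spec)
        if np.max(np.abs(f)) <= tol:
            break
        jac = -np.eye(W.n) + W.w * activation_derivative(y, spec)[None, :]
        try:
            step = np.linalg.solve(jac, -f)
        except np.linalg.LinAlgError as exc:
            raise NoEquilibriumError("singular Jacobian during Newton refinement") from exc
        y = y + step
        if not np.all(np.isfinite(y)):
            raise NoEquilibriumError("Newton iteration diverged to non-finite values")
    residual = float(np.max(np.abs(-y + W.w @ activation(y, spec))))
    if residual > 1e-10:
        raise NoEquilibriumError(
            f"no equilibrium found within {max_iter} Newton iterations "
            f"(final residual {residual:.3g})"
        )
    jac = -np.eye(W.n) + W.w * activation_derivative(y, spec)[None, :]
    eig = np.linalg.eigvals(jac)
    phi = activation(y, spec)
    return Equilibrium(
        state=y,
        active_set=frozenset(int(i) + 1 for i in np.nonzero(phi > 0.5)[0]),
        residual=residual,
        eigenvalues=eig,
        stable=bool(np.all(eig.real < 0)),
    )


def equilibrium_candidates(
    graph: DiGraph,
    params: ConstructionParams,
    spec: ActivationSpec,
    wp_overrides: dict | None = None,
) -> dict[int | str, Equilibrium]:
    """Refined one-active equilibria for every vertex, plus the all-off state.

    The all-off equilibrium near the origin (key ``"origin"``) is a genuine
    stable state of the system and must be distinguished from the vertex
    states when classifying trajectories.
    """
    W = build_weight_matrix(graph, params, wp_overrides)
    candidates: dict[int | str, Equilibrium] = {}
    for k in range(1, graph.n + 1):
        pred = predicted_equilibrium(graph, params, k)
        candidates[k] = refine_equilibrium(W, spec, pred.state)
    try:
        candidates["origin"] = refine_equilibrium(W, spec, np.zeros(graph.n))
    except NoEquilibriumError:
        pass
    return candidates


def _one_active_equilibrium_exists(
    W: WeightMatrix,
    spec: ActivationSpec,
    guess: np.ndarray,
    radius: float = 0.2,
) -> bool:
    """Does a stable equilibrium persist near the designed one-active state?

    Newton may converge to a different equilibrium (notably the all-off
    state) once the designed one has folded, so stability and proximity to
    the guess are required, not just convergence.
    """
    try:
        eq = refine_equilibrium(W, spec, guess)
    except NoEquilibriumError:
        return False
    return bool(eq.stable) and float(np.max(np.abs(eq.state - guess))) < radius


# ---------------------------------------------------------------------------
# Connection testing / realisation verification


@dataclass(frozen=True)
class TransitionOutcome:
    """Result of kicking cell ``kicked_cell`` while resting at ``xi_source``."""

    source: int
    kicked_cell: int
    classification: str  # "connected" | "returned" | "other"
    destination: int | None = None
    transit_time: float | None = None


@dataclass(frozen=True)
class RealisationReport:
    """Edge-by-edge certificate that a construction realises its graph."""

    delta: float
    edges: dict[tuple[int, int], TransitionOutcome] = field(default_factory=dict)
    non_edges: dict[tuple[int, int], TransitionOutcome] = field(default_factory=dict)

    @property
    def realised(self) -> bool:
        return all(o.classification == "connected" for o in self.edges.values()) and all(
            o.classification == "returned" for o in self.non_edges.values()
        )


#: trajectory accepted as converged to an equilibrium when it stays inside a
#: ball of radius delta * BALL_FRACTION for DWELL_TIME time units
BALL_FRACTION = 0.25
DWELL_TIME = 5.0


def test_connection(
    graph: DiGraph,
    params: ConstructionParams,
    spec: ActivationSpec,
    k: int,
    l: int,
    delta: float,
    horizon: float = 200.0,
    candidates: dict | None = None,
    tol: float = 1e-9,
) -> TransitionOutcome:
    """Kick cell ``l`` by ``delta`` from rest at ``xi_k`` and classify the fate.

    The input-free flow from ``xi_k + delta e_l`` is integrated until the
    state remains within ``delta/4`` of one refined equilibrium for 5
    consecutive time units.  Reaching ``xi_l`` is ``connected``, ``xi_k`` is
    ``returned``, anything else (another vertex state, the all-off state, or
    no settlement within ``horizon``) is ``other``.
    """
    if k == l:
        raise ValueError("source and kicked cell must differ")
    if candidates is None:
        candidates = equilibrium_candidates(graph, params, spec)
    W = build_weight_matrix(graph, params)
    ball = max(delta * BALL_FRACTION, 1e-6)
    y = kick(candidates[k].state, l, delta)

    names = list(candidates)
    points = np.array([candidates[m].state for m in names])
    all_times: list[np.ndarray] = []
    all_states: list[np.ndarray] = []
    t = 0.0
    winner = None
    while t < horizon and winner is None:
        chunk = simulate_ode(W, spec, y, t_max=DWELL_TIME, tol=tol)
        dists = np.max(np.abs(chunk.states[:, None, :] - points[None, :, :]), axis=2)
        inside = (dists < ball).all(axis=0)
        hits = np.nonzero(inside)[0]
        if hits.size:
            winner = names[hits[0]]
        all_times.append(chunk.times + t)
        all_states.append(chunk.states)
        y = chunk.final_state()
        t += DWELL_TIME

    if winner is None:
        return TransitionOutcome(k, l, "other", destination=None, transit_time=None)
    times = np.concatenate(all_times)
    states = np.vstack(all_states)
    target = candidates[winner].state
    entered = np.nonzero(np.max(np.abs(states - target), axis=1) < ball)[0]
    transit = float(times[entered[0]]) if entered.size else None
    if winner == l:
        return TransitionOutcome(k, l, "connected", destination=l, transit_time=transit)
    if winner == k:
        return TransitionOutcome(k, l, "returned", destination=k, transit_time=transit)
    dest = winner if isinstance(winner, int) else None
    return TransitionOutcome(k, l, "other", destination=dest, transit_time=transit)


def verify_realisation(
    graph: DiGraph,
    params: ConstructionParams,
    spec: ActivationSpec,
    delta: float,
    horizon: float = 200.0,
    tol: float = 1e-9,
) -> RealisationReport:
    """Test every ordered vertex pair: edges must connect, non-edges return."""
    candidates = equilibrium_candidates(graph, params, spec)
    edges: dict[tuple[int, int], TransitionOutcome] = {}
    non_edges: dict[tuple[int, int], TransitionOutcome] = {}
    for k in range(1, graph.n + 1):
        for l in range(1, graph.n + 1):
            if k == l:
                continue
            outcome = test_connection(
                graph, params, spec, k, l, delta, horizon, candidates=candidates, tol=tol
            )
            (edges if graph.has_edge(k, l) else non_edges)[(k, l)] = outcome
    return RealisationReport(delta=delta, edges=edges, non_edges=non_edges)


# ---------------------------------------------------------------------------
# Itineraries


@dataclass
class Itinerary:
    """Sequence of (time, active-cell set) events extracted from a trajectory."""

    events: list[tuple[float, frozenset[int]]]
    hysteresis: tuple[float, float]
    t_end: float

    def active_sets(self) -> list[frozenset[int]]:
        return [s for _, s in self.events]


def itinerary(
    traj: Trajectory,
    spec: ActivationSpec | None = None,
    on_level: float = 0.8,
    off_level: float = 0.2,
) -> Itinerary:
    """Hysteretic per-cell thresholding of the firing rates phi(y_j).

    A cell joins the active set when its rate rises through ``on_level`` and
    leaves when it falls through ``off_level``; an event is recorded whenever
    the set changes.  ``spec`` is required for ``y``-coordinate trajectories
    (to map through phi) and ignored for ``J``-coordinate ones.
    """
    if off_level >= on_level:
        raise ValueError("off_level must be below on_level")
    if traj.coords == "J":
        rates = traj.states
    else:
        if spec is None:
            raise ValueError("an ActivationSpec is required for y-coordinate trajectories")
        rates = activation(traj.states, spec)
    n = rates.shape[1]
    active = rates[0] > on_level
    events = [(float(traj.times[0]), frozenset(int(i) + 1 for i in np.nonzero(active)[0]))]
    on_mask = rates > on_level
    off_mask = rates < off_level
    for idx in range(1, rates.shape[0]):
        new_active = (active | on_mask[idx]) & ~off_mask[idx]
        if not np.array_equal(new_active, active):
            active = new_active
            events.append(
                (float(traj.times[idx]), frozenset(int(i) + 1 for i in np.nonzero(active)[0]))
            )
    return Itinerary(events=events, hysteresis=(on_level, off_level), t_end=float(traj.times[-1]))


def dwell_filtered_events(
    itin: Itinerary, min_dwell: float = 1.0
) -> list[tuple[float, frozenset[int]]]:
    """Drop active sets held for less than ``min_dwell`` time units.

    Fast threshold chatter during a transition (both cells briefly above the
    on-level) is thereby excluded; adjacent surviving duplicates are merged.
    """
    segments = []
    for i, (t, s) in enumerate(itin.events):
        t_next = itin.events[i + 1][0] if i + 1 < len(itin.events) else itin.t_end
        if t_next - t >= min_dwell:
            segments.append((t, s))
    merged: list[tuple[float, frozenset[int]]] = []
    for t, s in segments:
        if not merged or merged[-1][1] != s:
            merged.append((t, s))
    return merged


def double_activation_events(
    itin: Itinerary, graph: DiGraph, min_dwell: float = 1.0
) -> list[tuple[float, frozenset[int]]]:
    """Events where two cells with no connecting edge are active together.

    During an ordinary transition the outgoing and incoming Active cells --
    an edge pair -- overlap briefly above threshold; that is handover, not a
    state.  A genuine double-activation state (two sibling leading cells
    ignited together) involves a pair with no edge in either direction,
    which the construction's admissibility makes a clean discriminator.
    """
    out = []
    for t, s in dwell_filtered_events(itin, min_dwell):
        cells = sorted(s)
        if any(
            not graph.has_edge(i, j) and not graph.has_edge(j, i)
            for a, i in enumerate(cells)
            for j in cells[a + 1 :]
        ):
            out.append((t, s))
    return out


def estimate_period(itin: Itinerary, marker: frozenset[int] = frozenset({1}), min_dwell: float = 0.0):
    """Mean spacing of returns to the ``marker`` active set (steady portion).

    Uses the second half of the observed return intervals to discard the
    transient; raises if fewer than three returns are seen.
    """
    events = dwell_filtered_events(itin, min_dwell) if min_dwell > 0 else itin.events
    entries = [t for t, s in events if s == marker]
    if len(entries) < 3:
        raise ValueError(f"fewer than three returns to {set(marker)}; cannot estimate a period")
    gaps = np.diff(entries)
    tail = gaps[len(gaps) // 2 :]
    return float(np.mean(tail))


# ---------------------------------------------------------------------------
# Fold / SNIC thresholds


@dataclass(frozen=True)
class BifurcationResult:
    """Computed fold thresholds in ``w_p`` and related diagnostics."""

    wp_sn_closed: float
    x_minus: float
    x_plus: float
    wp_sn_numeric: float | None = None
    wp_snic: float | None = None
    wp_sn_prime: float | None = None
    eta: float | None = None
    dw: float | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _g(x, params: ConstructionParams):
    """g(x) = phi^{-1}(x) - w_s x, the slow-nullcline organising function."""
    spec = ActivationSpec.from_params(params, "smooth")
    return activation_inverse(x, spec) - params.w_s * np.asarray(x)


def _g_prime(x, params: ConstructionParams):
    x = np.asarray(x, dtype=float)
    return params.eps / (x * (1.0 - x)) - params.w_s


def _x_extrema(params: ConstructionParams) -> tuple[float, float]:
    if params.w_s <= 4 * params.eps:
        raise ValueError(
            f"nullcline extrema require w_s > 4 eps (got w_s={params.w_s}, eps={params.eps})"
        )
    r = np.sqrt(0.25 - params.eps / params.w_s)
    return 0.5 - r, 0.5 + r


def wp_sn_closed_form(eps: float, theta: float, w_s: float) -> float:
    """Asymptotic fold threshold of the two-cell system, through order eps^2::

        w_p^SN = eps ln(eps) + theta - eps (1 + ln w_s) + eps^2 / w_s
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if theta >= w_s:
        warnings.warn(
            f"closed form assumes theta < w_s (got theta={theta}, w_s={w_s}); "
            "the truncation may be unreliable",
            UserWarning,
        )
    return eps * np.log(eps) + theta - eps * (1.0 + np.log(w_s)) + eps**2 / w_s


def _require_smooth(spec: ActivationSpec) -> None:
    if spec.kind != "smooth":
        raise ValueError("this computation requires the smooth activation")


def wp_sn_numeric(params: ConstructionParams, spec: ActivationSpec) -> float:
    """Fold of the two-cell feed-forward system, located exactly.

    Solves the extended system {vector field = 0, det(Jacobian) = 0} in
    (y_1, y_2, w_p), seeded from the nullcline-extremum asymptotics; falls
    back to bisection on equilibrium existence if the extended Newton stalls.
    """
    _require_smooth(spec)
    if params.theta >= params.w_s:
        warnings.warn("fold location assumes theta < w_s", UserWarning)
    x_m, _ = _x_extrema(params)
    ws, wm = params.w_s, params.w_m
    wp0 = wp_sn_closed_form(params.eps, params.theta, params.w_s)
    y1_0 = ws + wm * x_m
    y2_0 = float(activation_inverse(x_m, spec))

    def extended(v):
        y1, y2, wp = v
        p1, p2 = activation(y1, spec), activation(y2, spec)
        d1, d2 = activation_derivative(y1, spec), activation_derivative(y2, spec)
        return [
            -y1 + ws * p1 + wm * p2,
            -y2 + ws * p2 + wp * p1,
            (-1.0 + ws * d1) * (-1.0 + ws * d2) - (wm * d2) * (wp * d1),
        ]

    sol = root(extended, [y1_0, y2_0, wp0], method="hybr", tol=1e-13)
    if sol.success and np.max(np.abs(extended(sol.x))) < 1e-9:
        return float(sol.x[2])

    # fallback: bisection on existence of the stable two-cell equilibrium
    two_cell = DiGraph.from_edges(2, [(1, 2)])

    def exists(wp: float) -> bool:
        p = params.replace(w_p=wp)
        W = build_weight_matrix(two_cell, p)
        return _one_active_equilibrium_exists(W, spec, np.array([ws + wm * x_m, y2_0]))

    lo, hi = wp0 - 0.02, wp0 + 0.02
    if not exists(lo) or exists(hi):
        raise NoEquilibriumError("fold detection failed: no sign change in fallback bracket")
    while hi - lo > 1e-10:
        mid = 0.5 * (lo + hi)
        lo, hi = (mid, hi) if exists(mid) else (lo, mid)
    return 0.5 * (lo + hi)


def snic_threshold_cycle(
    params: ConstructionParams,
    spec: ActivationSpec,
    bracket: tuple[float, float] | None = None,
    tol: float = 1e-6,
) -> float:
    """SNIC threshold of the three-cell cycle, by equilibrium-existence bisection.

    Below the returned ``w_p`` the cycle has three symmetric stable
    one-active equilibria (excitable regime); above it they are destroyed in
    three simultaneous folds on an invariant circle, leaving a periodic orbit
    whose period diverges at threshold.
    """
    _require_smooth(spec)
    cycle = DiGraph.from_edges(3, [(1, 2), (2, 3), (3, 1)])
    if bracket is None:
        bracket = (params.theta - 0.2, params.theta + 0.1)

    def exists(wp: float) -> bool:
        p = params.replace(w_p=wp)
        W = build_weight_matrix(cycle, p)
        guess = np.array([p.w_s, wp, p.w_m])
        return _one_active_equilibrium_exists(W, spec, guess)

    lo, hi = bracket
    if not exists(lo) or exists(hi):
        raise NoEquilibriumError(
            f"SNIC detection failed: no existence sign change over bracket {bracket}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        lo, hi = (mid, hi) if exists(mid) else (lo, mid)
    return 0.5 * (lo + hi)


def wp_sn_prime(
    w_t: float,
    dw: float,
    params: ConstructionParams,
    spec: ActivationSpec,
) -> float:
    """Fold threshold for a vertex with two leading cells (double activation).

    On the sheet where the active cell is saturated, the two leading rates
    (J_3, J_4) obey ``g(J_3) = w_p + dw + w_t J_4`` and
    ``g(J_4) = w_p + w_t J_3``; the returned ``w_p`` is where this pair of
    curves becomes tangent (extended system with det = g'(J_3) g'(J_4) -
    w_t^2 = 0).  Negative ``w_t`` (mutual suppression) pushes the fold to
    larger ``w_p``; positive ``w_t`` pulls it down.
    """
    _require_smooth(spec)
    x_m, _ = _x_extrema(params)
    g_max = float(_g(x_m, params))

    if w_t == 0.0:
        # decoupled: each leading direction folds at g(x_-); with dw > 0 the
        # boosted edge folds first
        return g_max - max(dw, 0.0)

    # Track the solution branch of the coupled pair that continues the stable
    # decoupled pair, stepping w_p upward until Newton loses it at the fold,
    # then bisect.  Unknowns are u with J = expit(u), so g(expit(u)) =
    # theta + eps*u - w_s*expit(u) is smooth on all of R and the iteration
    # cannot leave the domain.
    eps, th, ws = params.eps, params.theta, params.w_s

    def newton_pair(u, wp):
        u = np.array(u, dtype=float)
        converged = False
        for _ in range(60):
            j = expit(u)
            g = th + eps * u - ws * j
            f = np.array([g[0] - (wp + dw) - w_t * j[1], g[1] - wp - w_t * j[0]])
            if np.max(np.abs(f)) < 1e-13:
                converged = True
                break
            jj = j * (1.0 - j)
            jac = np.array(
                [[eps - ws * jj[0], -w_t * jj[1]], [-w_t * jj[0], eps - ws * jj[1]]]
            )
            try:
                step = np.linalg.solve(jac, -f)
            except np.linalg.LinAlgError:
                return None
            if not np.all(np.isfinite(step)) or np.max(np.abs(step)) > 50:
                return None
            u = u + step
        # accept only on the low-rate sheet (both J below 1/2): convergence
        # to the saturated branch is not the tracked pair
        if converged and np.max(expit(u)) < 0.5 and np.max(np.abs(u)) < 60:
            return u
        return None

    # start safely below the decoupled fold
    wp = g_max - max(dw, 0.0) - 0.02 - 0.1 * abs(w_t)
    target3 = wp + dw + w_t * x_m  # conservative decoupled-style seed
    j3_0 = brentq(lambda x: float(_g(x, params)) - target3, 1e-12, x_m) if target3 > float(
        _g(1e-12, params)
    ) else x_m / 2
    j4_0 = brentq(lambda x: float(_g(x, params)) - (wp + w_t * x_m), 1e-12, x_m)
    u = newton_pair([float(logit(j3_0)), float(logit(j4_0))], wp)
    if u is None:
        raise NoEquilibriumError("double-activation fold detection failed to initialise")
    step = 2e-3
    while True:
        trial = newton_pair(u, wp + step)
        if trial is None:
            break
        u, wp = trial, wp + step
        if wp > th + 0.2:
            raise NoEquilibriumError("double-activation fold not found below w_p = theta + 0.2")
    lo, hi = wp, wp + step
    while hi - lo > 1e-10:
        mid = 0.5 * (lo + hi)
        trial = newton_pair(u, mid)
        if trial is None:
            hi = mid
        else:
            u, lo = trial, mid
    return 0.5 * (lo + hi)


def lemma2_positions(eta: float, params: ConstructionParams) -> tuple[float, float]:
    """Predicted leading-cell rates just below the fold, ``w_p = w_p^SN - eta``.

    The pair of equilibria created in the fold sits at
    ``J_2 = eps/w_s -+ sqrt(2 eta eps)/w_s`` to leading order; valid for
    ``0 < eta << eps/4``.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    if eta >= params.eps / 4:
        warnings.warn(
            f"asymptotic positions assume eta << eps/4 (eta={eta}, eps={params.eps})",
            UserWarning,
        )
    centre = params.eps / params.w_s
    half = np.sqrt(2.0 * eta * params.eps) / params.w_s
    return centre - half, centre + half


# ---------------------------------------------------------------------------
# Bottlenecks, transition statistics, finite-state walks


def detect_bottlenecks(
    traj: Trajectory,
    W: WeightMatrix,
    spec: ActivationSpec,
    speed_ceiling: float = 0.1,
    speed_floor: float = 1e-4,
    refractory: float = 2.0,
) -> list[tuple[float, np.ndarray, float]]:
    """Slow passages past saddle-node ghosts along a deterministic trajectory.

    Returns strict local minima of ``|dy/dt|`` (2-norm) with speed between
    ``speed_floor`` (so rest at an equilibrium is not a passage) and
    ``speed_ceiling``; minima closer than ``refractory`` in time are merged,
    keeping the slowest.
    """
    if traj.coords != "y":
        raise ValueError("bottleneck detection expects a y-coordinate trajectory")
    speeds = np.linalg.norm(-traj.states + activation(traj.states, spec) @ W.w.T, axis=1)
    s = speeds
    interior = np.arange(1, len(s) - 1)
    is_min = (s[interior] < s[interior - 1]) & (s[interior] < s[interior + 1])
    idx = interior[is_min]
    idx = idx[(s[idx] > speed_floor) & (s[idx] < speed_ceiling)]
    found: list[tuple[float, np.ndarray, float]] = []
    for i in idx:
        t_i, v_i = float(traj.times[i]), float(s[i])
        if found and t_i - found[-1][0] < refractory:
            if v_i < found[-1][2]:
                found[-1] = (t_i, traj.states[i].copy(), v_i)
        else:
            found.append((t_i, traj.states[i].copy(), v_i))
    return found


def transition_statistics(
    itineraries: list[Itinerary],
    targets: list[frozenset[int] | set[int]],
    source: frozenset[int] | set[int] | None = None,
    min_dwell: float = 1.0,
) -> dict[str, dict[frozenset[int], float]]:
    """Count debounced entries into each target active set, with ratios.

    An entry is counted when the dwell-filtered active set changes to a
    target, optionally restricted to changes departing from ``source``.
    Ratios are normalised over the named targets (empty input gives zeros).
    """
    targets = [frozenset(t) for t in targets]
    source = frozenset(source) if source is not None else None
    counts = {t: 0 for t in targets}
    for itin in itineraries:
        seq = dwell_filtered_events(itin, min_dwell)
        for (_, prev), (_, cur) in zip(seq[:-1], seq[1:]):
            if source is not None and prev != source:
                continue
            if cur in counts:
                counts[cur] += 1
    total = sum(counts.values())
    ratios = {t: (c / total if total else 0.0) for t, c in counts.items()}
    return {"counts": counts, "ratios": ratios}


def execute_walk(
    graph: DiGraph,
    params: ConstructionParams,
    spec: ActivationSpec,
    walk: list[int],
    amplitude: float | None = None,
    duration: float = 1.0,
    settle: float = 30.0,
    tol: float = 1e-9,
) -> tuple[Itinerary, bool]:
    """Drive the network along a graph walk with input pulses; report success.

    Starting at rest in ``xi_{walk[0]}``, a rectangular pulse (default
    amplitude ``delta``) is applied to the next cell of the walk every
    ``settle`` time units.  Success means the dwell-filtered single-active
    itinerary spells out exactly the requested walk.
    """
    if len(walk) < 1:
        raise InvalidWalkError("walk must contain at least one vertex")
    for a, b in zip(walk[:-1], walk[1:]):
        if not graph.has_edge(a, b):
            raise InvalidWalkError(f"({a}->{b}) is not an edge of the graph")
    if amplitude is None:
        if params.delta is None:
            raise ValueError("no pulse amplitude given and params carry no delta")
        amplitude = params.delta

    W = build_weight_matrix(graph, params)
    start = refine_equilibrium(W, spec, predicted_equilibrium(graph, params, walk[0]).state)
    protocol = [
        PulseSpec(cell=l, start=settle * (i + 1), duration=duration, amplitude=amplitude)
        for i, l in enumerate(walk[1:])
    ]
    t_max = settle * len(walk)
    traj = simulate_ode(W, spec, start.state, protocol=protocol, t_max=t_max, tol=tol)
    itin = itinerary(traj, spec)
    # states dwell ~`settle` units; a dwell filter well above the O(1)
    # handover overlap but below the settle time isolates the visited states
    seq = dwell_filtered_events(itin, min_dwell=min(5.0, settle / 3))
    observed = [sorted(s) for _, s in seq]
    success = observed == [[v] for v in walk]
    return itin, success
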