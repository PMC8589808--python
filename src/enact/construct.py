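"""Weight-matrix synthesis and the one-active-cell equilibrium taxonomy.

Given an admissible directed graph with adjacency ``a`` the coupling matrix of
the CTRNN is assembled from four scalars::

    w_ij = w_t + (w_s - w_t) 1[i==j] + (w_p - w_t) a_ji + (w_m - w_t) a_ij

so that ``w_ii = w_s`` (self), ``w_ij = w_p`` if the graph has the edge
``j -> i`` (cell ``i`` leads from ``j``), ``w_ij = w_m`` if it has ``i -> j``
(cell ``i`` trails ``j``), and ``w_ij = w_t`` (transverse) otherwise.

The excitability-threshold recipe fixes all scalars from a single amplitude
``delta`` in (0, 1/2)::

    eps = delta/8,  theta = 1/2,  w_s = 1,  w_t = 0,
    w_p = theta - delta/2,  w_m = -(w_s - theta) - delta/2.

Under the recipe with the piecewise-affine activation, every vertex ``k`` of
the graph has an exactly computable stable equilibrium ``xi_k`` whose
components sit at one of four activity levels: Active ``Y_A = w_s``, Leading
``Y_L = w_p``, Trailing ``Y_T = w_m``, Disconnected ``Y_D = w_t``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .graphs import DiGraph, validate_graph

__all__ = [
    "ConstructionParams",
    "WeightMatrix",
    "ActivationSpec",
    "Equilibrium",
    "AdmissibilityError",
    "InadmissibleGraphWarning",
    "recipe_params",
    "build_weight_matrix",
    "activation",
    "activation_derivative",
    "activation_inverse",
    "predicted_equilibrium",
    "transition_cell_types",
]


class AdmissibilityError(ValueError):
    """Operation requires an admissible graph and the graph is not."""


class InadmissibleGraphWarning(UserWarning):
    """Emitted when a weight matrix is built for an inadmissible graph."""


@dataclass(frozen=True)
class ConstructionParams:
    """The six scalars of the construction, plus the recipe amplitude.

    ``delta`` is set when the parameters came from :func:`recipe_params`;
    directly supplied parameter sets need not satisfy any relation (their
    validity is established downstream by numerical verification).
    """

    eps: float
    theta: float
    w_s: float
    w_m: float
    w_p: float
    w_t: float
    delta: float | None = None

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError(f"eps must be positive, got {self.eps}")

    def replace(self, **kw) -> "ConstructionParams":
        d = {f: getattr(self, f) for f in ("eps", "theta", "w_s", "w_m", "w_p", "w_t", "delta")}
        d.update(kw)
        return ConstructionParams(**d)

    @property
    def levels(self) -> dict[str, float]:
        """Equilibrium activity levels keyed by role letter."""
        return {"A": self.w_s, "L": self.w_p, "T": self.w_m, "D": self.w_t}


def recipe_params(delta: float) -> ConstructionParams:
    """Parameters guaranteeing an excitable realisation with threshold ``delta``."""
    if not 0 < delta < 0.5:
        raise ValueError(f"delta must lie in (0, 1/2), got {delta}")
    theta, w_s = 0.5, 1.0
    return ConstructionParams(
        eps=delta / 8,
        theta=theta,
        w_s=w_s,
        w_m=-(w_s - theta) - delta / 2,
        w_p=theta - delta / 2,
        w_t=0.0,
        delta=delta,
    )


def default_smooth_params() -> ConstructionParams:
    """The default smooth-activation parameter point (recipe at delta=0.4)."""
    return recipe_params(0.4)


@dataclass(frozen=True)
class WeightMatrix:
    """Synthesised ``n x n`` coupling matrix with optional per-edge overrides.

    ``wp_overrides`` maps a graph edge ``(k, l)`` (1-based) to the replacement
    leading weight written at entry ``w[l-1, k-1]``.
    """

    w: np.ndarray
    wp_overrides: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.w.shape[0]

    def to_csv(self, path) -> None:
        np.savetxt(path, self.w, delimiter=",")


def build_weight_matrix(
    graph: DiGraph,
    params: ConstructionParams,
    wp_overrides: dict[tuple[int, int], float] | None = None,
    allow_inadmissible: bool = False,
) -> WeightMatrix:
    """Assemble the coupling matrix from the adjacency and four weights.

    ``wp_overrides[(k, l)]`` replaces the leading weight carried by the edge
    ``k -> l``, i.e. entry ``w[l-1, k-1]``, enabling edge-dependent
    excitability (the paired trailing entry is untouched).
    """
    report = validate_graph(graph)
    if not report.admissible:
        if not allow_inadmissible:
            raise AdmissibilityError(
                "graph is inadmissible (one-loops %s, two-loops %s, delta-cliques %s); "
                "pass allow_inadmissible=True to build anyway"
                % (report.one_loops, report.two_loops, report.delta_cliques)
            )
        warnings.warn("building weights for an inadmissible graph", InadmissibleGraphWarning)
    a = graph.adjacency.astype(float)
    wt, ws, wp, wm = params.w_t, params.w_s, params.w_p, params.w_m
    w = wt + (ws - wt) * np.eye(graph.n) + (wp - wt) * a.T + (wm - wt) * a
    overrides = dict(wp_overrides or {})
    for (k, l), value in overrides.items():
        if not graph.has_edge(k, l):
            raise KeyError(f"override keyed on non-edge ({k}->{l})")
        w[l - 1, k - 1] = value
    return WeightMatrix(w, overrides)


# ---------------------------------------------------------------------------
# Activation functions


@dataclass(frozen=True)
class ActivationSpec:
    """Sigmoid activation: logistic (``smooth``) or saturating piecewise-affine.

    Both kinds satisfy phi(theta) = 1/2 with maximum slope 1/(4 eps) at theta;
    the piecewise kind saturates exactly at 0 and 1 outside |y-theta| <= 2 eps.
    """

    kind: str
    eps: float
    theta: float

    def __post_init__(self) -> None:
        if self.kind not in ("smooth", "piecewise"):
            raise ValueError(f"kind must be 'smooth' or 'piecewise', got {self.kind!r}")
        if self.eps <= 0:
            raise ValueError(f"eps must be positive, got {self.eps}")

    @classmethod
    def from_params(cls, params: ConstructionParams, kind: str) -> "ActivationSpec":
        return cls(kind=kind, eps=params.eps, theta=params.theta)


def activation(y, spec: ActivationSpec):
    """phi(y), vectorised; values in [0, 1]."""
    y = np.asarray(y, dtype=float)
    if spec.kind == "smooth":
        return expit((y - spec.theta) / spec.eps)
    return np.clip((y - spec.theta) / (4 * spec.eps) + 0.5, 0.0, 1.0)


def activation_derivative(y, spec: ActivationSpec):
    """phi'(y); for the piecewise kind the slope 1/(4 eps) on |y-theta| <= 2 eps."""
    y = np.asarray(y, dtype=float)
    if spec.kind == "smooth":
        p = expit((y - spec.theta) / spec.eps)
        return p * (1.0 - p) / spec.eps
    return np.where(np.abs(y - spec.theta) <= 2 * spec.eps, 1.0 / (4 * spec.eps), 0.0)


def activation_inverse(x, spec: ActivationSpec):
    """phi^{-1}(x) = theta + eps * logit(x); smooth kind only, x in (0, 1)."""
    if spec.kind != "smooth":
        raise NotImplementedError("the piecewise activation is not invertible")
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or np.any(x >= 1):
        raise ValueError("activation_inverse requires x strictly inside (0, 1)")
    return spec.theta + spec.eps * logit(x)


# ---------------------------------------------------------------------------
# Predicted equilibria and cell roles

ROLES = ("A", "L", "T", "D")  # Active, Leading, Trailing, Disconnected


@dataclass
class Equilibrium:
    """A fixed point with per-cell activity roles and stability data."""

    state: np.ndarray
    active_set: frozenset[int]
    residual: float
    roles: tuple[str, ...] | None = None
    levels: dict[str, float] | None = None
    eigenvalues: np.ndarray | None = None
    stable: bool | None = None

    @property
    def n(self) -> int:
        return self.state.shape[0]


def _require_admissible(graph: DiGraph) -> None:
    report = validate_graph(graph)
    if not report.admissible:
        raise AdmissibilityError(
            "cell roles are only well defined for admissible graphs; violations: "
            f"one-loops {report.one_loops}, two-loops {report.two_loops}, "
            f"delta-cliques {report.delta_cliques}"
        )


def predicted_equilibrium(graph: DiGraph, params: ConstructionParams, k: int) -> Equilibrium:
    """The designed equilibrium ``xi_k`` with cell ``k`` Active.

    Roles follow the adjacency: ``k`` is Active; ``j`` is Leading iff the
    graph has ``k -> j``, Trailing iff it has ``j -> k``, else Disconnected.
    State components are placed exactly at the four levels; under the recipe
    with piecewise activation this point is an exact fixed point (residual 0).
    """
    _require_admissible(graph)
    if not 1 <= k <= graph.n:
        raise ValueError(f"vertex {k} outside 1..{graph.n}")
    a = graph.adjacency
    roles = []
    for j in range(1, graph.n + 1):
        if j == k:
            roles.append("A")
        elif a[k - 1, j - 1]:
            roles.append("L")
        elif a[j - 1, k - 1]:
            roles.append("T")
        else:
            roles.append("D")
    levels = params.levels
    state = np.array([levels[r] for r in roles])
    W = build_weight_matrix(graph, params)
    spec = ActivationSpec.from_params(params, "piecewise")
    res = float(np.max(np.abs(-state + W.w @ activation(state, spec))))
    return Equilibrium(
        state=state,
        active_set=frozenset({k}),
        residual=res,
        roles=tuple(roles),
        levels=levels,
    )


#: transition role labels for a transition k -> l, keyed by the adjacency
#: pattern (a_jk, a_kj, a_jl, a_lj) of a bystander cell j
_TRANSITION_CASES = {
    (0, 0, 0, 0): "DD",
    (1, 0, 0, 0): "TD",
    (0, 1, 0, 0): "LD",
    (1, 0, 0, 1): "TL",
    (0, 0, 1, 0): "DT",
    (0, 0, 0, 1): "DL",
}


def transition_cell_types(graph: DiGraph, k: int, l: int) -> tuple[str, ...]:
    """Classify every cell's role change during the transition ``k -> l``.

    Cell ``k`` is AT (Active becomes Trailing), cell ``l`` is LA (Leading
    becomes Active); the six remaining patterns of the adjacency entries
    ``(a_jk, a_kj, a_jl, a_lj)`` are the only ones admissibility permits.
    """
    _require_admissible(graph)
    a = graph.adjacency
    if not graph.has_edge(k, l):
        raise ValueError(f"({k}->{l}) is not an edge of the graph")
    labels = []
    for j in range(1, graph.n + 1):
        if j == k:
            labels.append("AT")
        elif j == l:
            labels.append("LA")
        else:
            pattern = (
                int(a[j - 1, k - 1]),
                int(a[k - 1, j - 1]),
                int(a[j - 1, l - 1]),
                int(a[l - 1, j - 1]),
            )
            try:
                labels.append(_TRANSITION_CASES[pattern])
            except KeyError:
                raise RuntimeError(
                    f"cell {j} has adjacency pattern {pattern} relative to transition "
                    f"{k}->{l}, which admissibility excludes; the graph is corrupted"
                ) from None
    return tuple(labels)
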