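"""Vector fields and deterministic / stochastic integration of the CTRNN.

The model in the native (``y``) coordinates is::

    dy_i/dt = -y_i + sum_j w_ij phi(y_j) + I_i(t)

with additive noise entering as ``sigma dW_i(t)`` (independent Wiener
processes) in the stochastic variant.  For the smooth activation there is an
equivalent description in the firing-rate coordinates ``J_i = phi(y_i)``::

    dJ_i/dt = (1/eps) J_i (1 - J_i) ( -phi^{-1}(J_i) + sum_j w_ij J_j )

valid on the open cube ``J in (0,1)^n`` and only for the input-free system.

Deterministic runs use an adaptive Runge--Kutta scheme with dense output (the
piecewise-affine activation is continuous, so no event handling is needed);
stochastic runs use fixed-step Euler--Maruyama with a seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import expit

from .construct import ActivationSpec, WeightMatrix, activation, activation_inverse

__all__ = [
    "Trajectory",
    "PulseSpec",
    "vector_field",
    "simulate_ode",
    "simulate_sde",
    "kick",
]

#: maximum spacing of returned samples, dense enough for itinerary extraction
SAMPLE_SPACING = 0.1


@dataclass(frozen=True)
class PulseSpec:
    """A rectangular input pulse on one cell; overlapping pulses sum."""

    cell: int
    start: float
    duration: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"pulse duration must be positive, got {self.duration}")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass
class Trajectory:
    """Time-sampled solution path in ``y`` or ``J`` coordinates."""

    times: np.ndarray
    states: np.ndarray
    coords: str = "y"
    seed: int | None = None
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.states.shape[0] != self.times.shape[0]:
            raise ValueError("states must have one row per sample time")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.states.shape[1]

    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_tsv(self, path) -> None:
        header = "t\t" + "\t".join(
            f"{self.coords}{i}" for i in range(1, self.n + 1)
        )
        np.savetxt(
            Path(path),
            np.column_stack([self.times, self.states]),
            delimiter="\t",
            header=header,
            comments="",
        )


def _pulse_input(protocol: list[PulseSpec], n: int, t: float) -> np.ndarray:
    out = np.zeros(n)
    for p in protocol:
        if p.start <= t < p.end:
            out[p.cell - 1] += p.amplitude
    return out


def vector_field(
    state: np.ndarray,
    W: WeightMatrix,
    spec: ActivationSpec,
    t: float = 0.0,
    protocol: list[PulseSpec] | None = None,
    coords: str = "y",
) -> np.ndarray:
    """Instantaneous derivative in the chosen coordinates.

    The ``J`` form requires the smooth activation, components strictly inside
    (0,1), and no input (it is derived for the input-free system only).
    """
    state = np.asarray(state, dtype=float)
    if coords == "y":
        field = -state + W.w @ activation(state, spec)
        if protocol:
            field = field + _pulse_input(protocol, state.shape[0], t)
        return field
    if coords == "J":
        if spec.kind != "smooth":
            raise ValueError("J-coordinates require the smooth activation")
        if protocol:
            raise NotImplementedError("inputs are not supported in J-coordinates")
        if np.any(state <= 0) or np.any(state >= 1):
            raise ValueError("J components must lie strictly inside (0, 1)")
        return (
            state
            * (1.0 - state)
            * (-activation_inverse(state, spec) + W.w @ state)
            / spec.eps
        )
    raise ValueError(f"coords must be 'y' or 'J', got {coords!r}")


def simulate_ode(
    W: WeightMatrix,
    spec: ActivationSpec,
    y0: np.ndarray,
    protocol: list[PulseSpec] | None = None,
    t_max: float = 100.0,
    tol: float = 1e-9,
    coords: str = "y",
) -> Trajectory:
    """Integrate the deterministic system with an adaptive RK scheme.

    Output is sampled at spacing :data:`SAMPLE_SPACING`.  The time axis is
    split at every pulse edge so the discontinuous input never crosses an
    integrator step.  Bit-stable for fixed inputs and tolerances.
    """
    y0 = np.asarray(y0, dtype=float)
    if t_max < 0:
        raise ValueError("t_max must be non-negative")
    if t_max == 0:
        return Trajectory(np.array([0.0]), y0[None, :].copy(), coords=coords)
    protocol = list(protocol or [])
    if protocol and coords == "J":
        raise NotImplementedError("inputs are not supported in J-coordinates")

    edges = sorted(
        {0.0, t_max}
        | {p.start for p in protocol if 0 < p.start < t_max}
        | {p.end for p in protocol if 0 < p.end < t_max}
    )
    rhs = lambda t, y: vector_field(y, W, spec, t=t, protocol=protocol, coords=coords)
    times = [np.array([0.0])]
    states = [y0[None, :]]
    y = y0
    for a, b in zip(edges[:-1], edges[1:]):
        n_samples = max(2, int(np.ceil((b - a) / SAMPLE_SPACING)) + 1)
        t_eval = np.linspace(a, b, n_samples)
        sol = solve_ivp(
            rhs, (a, b), y, method="RK45", t_eval=t_eval, rtol=tol, atol=tol,
            max_step=max((b - a) / 4, 1.0),
        )
        if not sol.success:
            raise RuntimeError(f"integration failed near t={sol.t[-1]:.6g}: {sol.message}")
        times.append(sol.t[1:])
        states.append(sol.y.T[1:])
        y = sol.y[:, -1]
    return Trajectory(np.concatenate(times), np.vstack(states), coords=coords)


def simulate_sde(
    W: WeightMatrix,
    spec: ActivationSpec,
    y0: np.ndarray,
    sigma: float,
    t_max: float,
    dt: float = 0.01,
    seed: int | None = None,
    save_every: int = 1,
) -> Trajectory:
    """Euler--Maruyama path of the CTRNN with additive noise.

    Reproducible given ``seed``; with ``sigma=0`` the path is exactly the
    fixed-step deterministic Euler path (the noise term contributes 0.0).
    ``save_every`` thins the stored samples (the integration step is ``dt``
    regardless).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t_max < dt:
        raise ValueError("t_max must be at least dt")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma > 0 and seed is None:
        raise ValueError("a seed is mandatory for noisy runs")
    y = np.asarray(y0, dtype=float).copy()
    n = y.shape[0]
    n_steps = int(round(t_max / dt))
    rng = np.random.default_rng(seed)
    sqrt_dt = np.sqrt(dt)
    w = W.w
    theta, eps = spec.theta, spec.eps
    smooth = spec.kind == "smooth"
    keep = range(0, n_steps + 1, save_every)
    out = np.empty((len(keep), n))
    out[0] = y
    times = np.array([i * dt for i in keep])
    row = 1
    for step in range(1, n_steps + 1):
        if smooth:
            phi = expit((y - theta) / eps)
        else:
            phi = np.clip((y - theta) / (4 * eps) + 0.5, 0.0, 1.0)
        drift = -y + w @ phi
        noise = sigma * sqrt_dt * rng.standard_normal(n) if sigma > 0 else 0.0
        y = y + drift * dt + noise
        if step % save_every == 0:
            out[row] = y
            row += 1
    return Trajectory(times, out, coords="y", seed=seed, sigma=sigma)


def kick(state: np.ndarray, cell: int, delta: float) -> np.ndarray:
    """Instantaneous perturbation ``state + delta * e_cell`` (1-based cell)."""
    state = np.asarray(state, dtype=float)
    if not 1 <= cell <= state.shape[0]:
        raise ValueError(f"cell {cell} outside 1..{state.shape[0]}")
    out = state.copy()
    out[cell - 1] += delta
    return out
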