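"""Fixed-step integration schemes for the DC model.

Five schemes, all written directly against the affine system
``x' = A x + b``: explicit (forward) Euler, implicit (backward) Euler,
Heun's predictor-corrector, classical 4th-order Runge-Kutta, and the
4th-order Adams-Bashforth-Moulton predictor-corrector (PECE, RK4
start-up).  No adaptive stepping anywhere: step-size effects are the
object of study, not a nuisance to control away.

Because the system is linear, each one-step scheme acts on the deviation
from equilibrium through its stability function evaluated at the modal
arguments ``dt * eta1`` and ``dt * eta2``; :func:`amplification` exposes
those per-mode growth factors as the stability diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .analytic import propagate
from .model import ModelParameters, State, derived_constants

__all__ = [
    "InsufficientHistoryError",
    "METHODS",
    "Trajectory",
    "AmplificationReport",
    "step_explicit_euler",
    "step_implicit_euler",
    "step_heun",
    "step_rk4",
    "step_abm4",
    "integrate",
    "amplification",
]

#: Population scale beyond which a trajectory is declared divergent
#: (>1000x any plausible national diabetic population).
DIVERGENCE_THRESHOLD = 1e12

METHODS = ("explicit_euler", "implicit_euler", "heun", "rk4", "abm4", "analytic")


class InsufficientHistoryError(ValueError):
    """ABM4 needs exactly 4 consecutive states of history."""


@dataclass(frozen=True)
class Trajectory:
    """Uniform-grid solution of one scheme.

    ``states`` starts at the supplied initial state and advances in steps of
    ``dt``.  ``diverged`` is set (and the trajectory truncated) at the first
    state whose magnitude exceeds the divergence threshold or is non-finite.
    """

    method: str
    dt: float
    states: tuple[State, ...]
    diverged: bool = False
    diverged_at: float | None = None

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.states])

    @property
    def C(self) -> np.ndarray:
        return np.array([s.C for s in self.states])

    @property
    def N(self) -> np.ndarray:
        return np.array([s.N for s in self.states])

    def at_time(self, t: float, rel_tol: float = 1e-9) -> State:
        """State at grid time ``t`` (must lie on the grid)."""
        for s in self.states:
            if abs(s.t - t) <= rel_tol * max(1.0, abs(t)):
                return s
        raise KeyError(f"time {t} not on the trajectory grid")


@dataclass(frozen=True)
class AmplificationReport:
    """Per-mode growth factors of a scheme at a given step size.

    ``factors[i]`` multiplies the component along mode ``eta_i`` each step;
    ``stable`` means the spectral radius (largest magnitude) is <= 1.  For
    the analytic propagator the factors are exactly ``exp(-eta * dt)``.
    """

    method: str
    dt: float
    factors: tuple[float, float]
    spectral_radius: float
    stable: bool


def _f(x: np.ndarray, A: np.ndarray, b: np.ndarray) -> np.ndarray:
    return A @ x + b


def step_explicit_euler(state: State, dt: float, params: ModelParameters) -> State:
    """One forward-Euler step: ``x_{i+1} = x_i + dt (A x_i + b)``."""
    A, b = params.system_matrix(), params.forcing()
    x = state.as_array()
    x = x + dt * _f(x, A, b)
    return State(t=state.t + dt, C=float(x[0]), N=float(x[1]))


def step_implicit_euler(
    state: State, dt: float, params: ModelParameters, gauss_seidel: bool = False
) -> State:
    """One backward-Euler step.

    The update equations for C and N are mutually coupled; by default the
    coupled 2x2 linear system ``(I - dt A) x_{i+1} = x_i + dt b`` is solved
    exactly.  ``gauss_seidel=True`` instead performs a single sweep — C from
    the lagged N, then N from the new C — for fidelity experiments with the
    sequential update some implementations use.
    """
    A, b = params.system_matrix(), params.forcing()
    x = state.as_array()
    if gauss_seidel:
        lam, theta, mu = params.lambda_, params.theta, params.mu
        nd = params.nu + params.delta
        I = params.incidence
        C_new = (dt * (I + lam * x[1]) + x[0]) / (1.0 + dt * (lam + theta))
        N_new = (dt * (2.0 * I - nd * C_new) + x[1]) / (1.0 + dt * mu)
        return State(t=state.t + dt, C=C_new, N=N_new)
    M = np.eye(2) - dt * A
    x = np.linalg.solve(M, x + dt * b)
    return State(t=state.t + dt, C=float(x[0]), N=float(x[1]))


def step_heun(state: State, dt: float, params: ModelParameters) -> State:
    """One Heun (explicit trapezoidal) step: Euler predictor, averaged corrector."""
    A, b = params.system_matrix(), params.forcing()
    x = state.as_array()
    f0 = _f(x, A, b)
    xp = x + dt * f0
    x = x + 0.5 * dt * (f0 + _f(xp, A, b))
    return State(t=state.t + dt, C=float(x[0]), N=float(x[1]))


def step_rk4(state: State, dt: float, params: ModelParameters) -> State:
    """One classical RK4 step (half-step stages 2-3, full-step stage 4)."""
    A, b = params.system_matrix(), params.forcing()
    x = state.as_array()
    k1 = _f(x, A, b)
    k2 = _f(x + 0.5 * dt * k1, A, b)
    k3 = _f(x + 0.5 * dt * k2, A, b)
    k4 = _f(x + dt * k3, A, b)
    x = x + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return State(t=state.t + dt, C=float(x[0]), N=float(x[1]))


def step_abm4(history: Sequence[State], dt: float, params: ModelParameters) -> State:
    """One 4th-order Adams-Bashforth-Moulton PECE step.

    ``history`` holds the last four states (oldest first) at spacing ``dt``.
    Predict with the Adams-Bashforth 4-step formula, re-evaluate the
    derivative at the predictor, correct with the Adams-Moulton formula.
    """
    if len(history) != 4:
        raise InsufficientHistoryError(
            f"ABM4 needs exactly 4 prior states, got {len(history)}"
        )
    A, b = params.system_matrix(), params.forcing()
    xs = [s.as_array() for s in history]
    fs = [_f(x, A, b) for x in xs]
    xp = xs[3] + dt / 24.0 * (55.0 * fs[3] - 59.0 * fs[2] + 37.0 * fs[1] - 9.0 * fs[0])
    fp = _f(xp, A, b)
    x = xs[3] + dt / 24.0 * (9.0 * fp + 19.0 * fs[3] - 5.0 * fs[2] + fs[1])
    return State(t=history[3].t + dt, C=float(x[0]), N=float(x[1]))


_ONE_STEP: dict[str, Callable[[State, float, ModelParameters], State]] = {
    "explicit_euler": step_explicit_euler,
    "implicit_euler": step_implicit_euler,
    "heun": step_heun,
    "rk4": step_rk4,
}


def _is_divergent(s: State) -> bool:
    return (
        not np.isfinite(s.C)
        or not np.isfinite(s.N)
        or abs(s.C) > DIVERGENCE_THRESHOLD
        or abs(s.N) > DIVERGENCE_THRESHOLD
    )


def integrate(
    method: str,
    state0: State,
    params: ModelParameters,
    dt: float,
    t_end: float,
) -> Trajectory:
    """Integrate from ``state0`` to ``t_end`` on the uniform grid of step ``dt``.

    ``t_end`` must equal ``state0.t + k * dt`` for integer ``k``.  The
    ``"analytic"`` method delegates each grid point to the exact propagator.
    ABM4 bootstraps its first three steps with RK4 and then slides a 4-state
    window.  Divergence (non-finite values or magnitudes beyond 1e12) is
    recorded and truncates the trajectory; it is never raised.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    span = t_end - state0.t
    if span < 0:
        raise ValueError("t_end must be >= state0.t")
    n_steps = round(span / dt)
    if abs(n_steps * dt - span) > 1e-9 * max(1.0, abs(span)):
        raise ValueError(f"t_end - t0 = {span} is not an integer multiple of dt = {dt}")

    states = [state0]
    diverged = False
    diverged_at: float | None = None

    def push(s: State) -> bool:
        nonlocal diverged, diverged_at
        states.append(s)
        if _is_divergent(s):
            diverged = True
            diverged_at = s.t
            return False
        return True

    if method == "analytic":
        for i in range(1, n_steps + 1):
            states.append(propagate(state0, i * dt, params))
    elif method == "abm4":
        for _ in range(min(3, n_steps)):
            if not push(step_rk4(states[-1], dt, params)):
                break
        while len(states) < n_steps + 1 and not diverged:
            if not push(step_abm4(states[-4:], dt, params)):
                break
    else:
        step = _ONE_STEP[method]
        for _ in range(n_steps):
            if not push(step(states[-1], dt, params)):
                break
    return Trajectory(
        method=method,
        dt=dt,
        states=tuple(states),
        diverged=diverged,
        diverged_at=diverged_at,
    )


def _stability_function(method: str, x: float) -> float:
    """Growth factor of a scheme on the scalar test problem y' = -eta y, x = eta dt."""
    if method == "explicit_euler":
        return 1.0 - x
    if method == "implicit_euler":
        return 1.0 / (1.0 + x)
    if method == "heun":
        return 1.0 - x + x * x / 2.0
    if method == "rk4":
        return 1.0 - x + x**2 / 2.0 - x**3 / 6.0 + x**4 / 24.0
    if method == "analytic":
        return float(np.exp(-x))
    if method == "abm4":
        # PECE characteristic polynomial: substitute the AB4 predictor into
        # the AM4 corrector on y' = -eta y and collect the 4-term recurrence.
        c = x / 24.0
        poly = [
            1.0,
            -(1.0 - 28.0 * c + 9.0 * 55.0 * c * c),
            -(5.0 * c - 9.0 * 59.0 * c * c),
            -(-c + 9.0 * 37.0 * c * c),
            -(-(9.0 * 9.0) * c * c),
        ]
        roots = np.roots(poly)
        return float(np.max(np.abs(roots)))
    raise ValueError(f"unknown method {method!r}")


def amplification(method: str, params: ModelParameters, dt: float) -> AmplificationReport:
    """Per-mode growth factors of ``method`` at step ``dt`` for these parameters."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    k = derived_constants(params)
    factors = tuple(_stability_function(method, dt * eta) for eta in (k.eta1, k.eta2))
    radius = max(abs(f) for f in factors)
    return AmplificationReport(
        method=method,
        dt=dt,
        factors=factors,  # type: ignore[arg-type]
        spectral_radius=radius,
        stable=radius <= 1.0,
    )
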