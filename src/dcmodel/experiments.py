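"""Reproducible study pipelines: error tables, step-size and parameter
sweeps, and the incidence x lambda scenario grid.

Every numerical trajectory is scored against the exact affine propagator
(:func:`dcmodel.analytic.propagate`); percentage errors are
``|numeric - true| / true * 100``.  The default error-table setup anchors at
the t = 5 reference state and reports t = 5, 10, 15, 20 with a one-year
step, mirroring the canonical analysis window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .analytic import propagate
from .model import ModelParameters, State, equilibrium, initial_conditions
from .solvers import Trajectory, amplification, integrate
from .stability import analyze

__all__ = [
    "ErrorTable",
    "SweepResult",
    "ScenarioGrid",
    "percentage_error",
    "error_table",
    "dt_sweep",
    "param_sweep",
    "incidence_grid",
]

DEFAULT_REPORT_TIMES = (5.0, 10.0, 15.0, 20.0)
DEFAULT_DT_GRID = (0.1, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5)
DEFAULT_INCIDENCE_LEVELS = (2e6, 3e6, 6e6)
DEFAULT_LAMBDA_LEVELS = (0.3, 0.4, 0.5)

ERROR_TABLE_COLUMNS = [
    "t",
    "C_num",
    "C_true",
    "err_C_pct",
    "N_num",
    "N_true",
    "err_N_pct",
]


def percentage_error(num: float, truth: float) -> float:
    """``|num - truth| / |truth| * 100``; undefined for truth = 0."""
    if truth == 0:
        raise ZeroDivisionError("percentage error undefined for a zero true value")
    return abs(num - truth) / abs(truth) * 100.0


@dataclass(frozen=True)
class ErrorTable:
    """Numeric-vs-true comparison of one scheme at the reporting times."""

    method: str
    dt: float
    frame: pd.DataFrame  # ERROR_TABLE_COLUMNS, one row per reporting time
    avg_err_C_pct: float
    avg_err_N_pct: float

    def with_average_row(self) -> pd.DataFrame:
        """Frame plus a trailing average-error row (t = NaN)."""
        avg = pd.DataFrame(
            [
                {
                    "t": np.nan,
                    "C_num": np.nan,
                    "C_true": np.nan,
                    "err_C_pct": self.avg_err_C_pct,
                    "N_num": np.nan,
                    "N_true": np.nan,
                    "err_N_pct": self.avg_err_N_pct,
                }
            ]
        )
        return pd.concat([self.frame, avg], ignore_index=True)


@dataclass(frozen=True)
class SweepResult:
    """Outcome of sweeping one axis (dt or a model parameter)."""

    axis: str
    values: tuple[float, ...]
    frame: pd.DataFrame
    trajectories: tuple[Trajectory, ...] = ()


@dataclass(frozen=True)
class ScenarioGrid:
    """(C, N) projections over an incidence x lambda grid."""

    horizon: float | None  # None = equilibrium (infinite horizon)
    C: pd.DataFrame  # index: lambda levels, columns: incidence levels
    N: pd.DataFrame


def error_table(
    method: str,
    anchor_state: State,
    params: ModelParameters,
    dt: float = 1.0,
    report_times: Sequence[float] = DEFAULT_REPORT_TIMES,
) -> ErrorTable:
    """Run ``method`` from the anchor and tabulate errors against the exact
    propagator at ``report_times`` (which must lie on the step grid)."""
    t_end = max(report_times)
    traj = integrate(method, anchor_state, params, dt, t_end)
    rows = []
    for t in report_times:
        s = traj.at_time(t)
        truth = propagate(anchor_state, t - anchor_state.t, params)
        rows.append(
            {
                "t": t,
                "C_num": s.C,
                "C_true": truth.C,
                "err_C_pct": percentage_error(s.C, truth.C),
                "N_num": s.N,
                "N_true": truth.N,
                "err_N_pct": percentage_error(s.N, truth.N),
            }
        )
    frame = pd.DataFrame(rows, columns=ERROR_TABLE_COLUMNS)
    return ErrorTable(
        method=method,
        dt=dt,
        frame=frame,
        avg_err_C_pct=float(frame["err_C_pct"].mean()),
        avg_err_N_pct=float(frame["err_N_pct"].mean()),
    )


def dt_sweep(
    methods: Sequence[str],
    dts: Sequence[float] = DEFAULT_DT_GRID,
    params: ModelParameters | None = None,
    state0: State | None = None,
    t_end: float | None = None,
) -> SweepResult:
    """End-state error and amplification-based stability verdict per
    (method, dt) cell.

    ``t_end`` defaults to the largest grid time <= 20 reachable from the
    anchor with every requested dt (each dt keeps its own integer-step
    horizon when the spans differ).
    """
    params = params or ModelParameters()
    if state0 is None:
        from .scenarios import anchored_truth_fixture

        state0 = anchored_truth_fixture().state
    horizon = 20.0 if t_end is None else t_end
    rows = []
    for method in methods:
        for dt in dts:
            n_steps = int(np.floor((horizon - state0.t) / dt + 1e-9))
            end = state0.t + n_steps * dt
            traj = integrate(method, state0, params, dt, end)
            report = amplification(method, params, dt)
            last = traj.states[-1]
            truth = propagate(state0, last.t - state0.t, params)
            rows.append(
                {
                    "method": method,
                    "dt": dt,
                    "t_end": last.t,
                    "err_C_pct": np.nan if traj.diverged else percentage_error(last.C, truth.C),
                    "err_N_pct": np.nan if traj.diverged else percentage_error(last.N, truth.N),
                    "diverged": traj.diverged,
                    "spectral_radius": report.spectral_radius,
                    "stable": report.stable,
                }
            )
    return SweepResult(axis="dt", values=tuple(dts), frame=pd.DataFrame(rows))


def param_sweep(
    param_name: str,
    values: Sequence[float],
    base_params: ModelParameters | None = None,
    dt: float = 1.0,
    horizon: float = 20.0,
    offset: float = 500.0,
) -> SweepResult:
    """Equilibrium, eigenvalues and an RK4 trajectory per swept value.

    Initial conditions are re-derived from each swept parameter set's own
    equilibrium (offset +500 persons) so trajectories reflect the swept
    dynamics.  A lambda above 1 is accepted as a rate (not a probability)
    with a warning.
    """
    base_params = base_params or ModelParameters()
    field = {"lambda": "lambda_", "gamma": "gamma", "delta": "delta", "mu": "mu", "nu": "nu"}
    if param_name not in field:
        raise ValueError(f"unknown sweep parameter {param_name!r}")
    rows = []
    trajs = []
    for v in values:
        if param_name == "lambda" and v > 1.0:
            warnings.warn(
                f"lambda = {v} exceeds 1; interpreted as a rate, not a probability",
                stacklevel=2,
            )
        params = base_params.replace(**{field[param_name]: v})
        eq = equilibrium(params, "ode_consistent")
        report = analyze(params)
        state0 = initial_conditions(params, offset, offset)
        n_steps = int(np.floor(horizon / dt + 1e-9))
        traj = integrate("rk4", state0, params, dt, n_steps * dt)
        trajs.append(traj)
        last = traj.states[-1]
        truth = propagate(state0, last.t - state0.t, params)
        rows.append(
            {
                param_name: v,
                "C_star": eq.C_star,
                "N_star": eq.N_star,
                "chi1": complex(report.chi1).real,
                "chi2": complex(report.chi2).real,
                "C_end": last.C,
                "N_end": last.N,
                "err_C_pct": np.nan if traj.diverged else percentage_error(last.C, truth.C),
                "diverged": traj.diverged,
            }
        )
    return SweepResult(
        axis=param_name,
        values=tuple(values),
        frame=pd.DataFrame(rows),
        trajectories=tuple(trajs),
    )


def incidence_grid(
    I_levels: Sequence[float] = DEFAULT_INCIDENCE_LEVELS,
    lambda_levels: Sequence[float] = DEFAULT_LAMBDA_LEVELS,
    base_params: ModelParameters | None = None,
    horizon: float | None = None,
) -> ScenarioGrid:
    """(C, N) per (incidence, lambda) cell.

    ``horizon=None`` reports the equilibrium (the infinite-horizon
    projection); a finite horizon propagates exactly from each cell's own
    equilibrium-plus-500 initial condition.  Both C and N scale exactly
    linearly in incidence down each column.
    """
    base_params = base_params or ModelParameters()
    C = pd.DataFrame(index=list(lambda_levels), columns=list(I_levels), dtype=float)
    N = pd.DataFrame(index=list(lambda_levels), columns=list(I_levels), dtype=float)
    C.index.name = N.index.name = "lambda"
    C.columns.name = N.columns.name = "incidence"
    for lam in lambda_levels:
        for I in I_levels:
            params = base_params.replace(lambda_=lam, incidence=I)
            if I == 0:
                C.loc[lam, I] = 0.0
                N.loc[lam, I] = 0.0
                continue
            if horizon is None:
                eq = equilibrium(params, "ode_consistent")
                C.loc[lam, I], N.loc[lam, I] = eq.C_star, eq.N_star
            else:
                state0 = initial_conditions(params, 500.0, 500.0)
                s = propagate(state0, horizon, params)
                C.loc[lam, I], N.loc[lam, I] = s.C, s.N
    return ScenarioGrid(horizon=horizon, C=C, N=N)
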