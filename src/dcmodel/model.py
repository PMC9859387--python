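"""Core definition of the diabetes-complications (DC) compartmental model.

The diabetic population is split into two compartments: people living with
diabetes-related complications, ``C(t)``, and people without complications,
``D(t)``; the total stock of diabetics is ``N(t) = C(t) + D(t)``.  New cases
enter at a constant incidence ``I`` (persons/year), complications develop at
rate ``lambda``, are brought under control at rate ``gamma``, and people leave
through natural mortality ``mu``, complication-related mortality ``delta`` and
severe disability ``nu``.

In the ``(C, N)`` coordinates the dynamics are the affine linear system

    C'(t) = I - (lambda + theta) C(t) + lambda N(t)
    N'(t) = 2 I - (nu + delta) C(t) - mu N(t)

with ``theta = gamma + mu + nu + delta``, i.e. ``x' = A x + b`` for a constant
2x2 matrix ``A`` and forcing ``b = (I, 2I)``.  Everything downstream — the
closed-form solution, the numerical schemes and the stability analysis — works
on this system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ComplexModesError",
    "SingularSystemError",
    "ModelParameters",
    "State",
    "DerivedConstants",
    "Equilibrium",
    "rhs",
    "rhs_dc",
    "derived_constants",
    "equilibrium",
    "initial_conditions",
]


class ComplexModesError(ValueError):
    """The spectrum is complex (sigma^2 < 4 beta); no real decay rates exist."""


class SingularSystemError(ValueError):
    """The system matrix is singular (beta = 0); no unique equilibrium."""


@dataclass(frozen=True)
class ModelParameters:
    """Rates and incidence of the DC model.

    All rates are per year; ``incidence`` is persons per year.  Defaults are
    the canonical parameterisation used throughout the analysis.

    Attributes
    ----------
    lambda_ : probability of developing a complication (per year)
    delta : mortality rate due to complications (per year)
    mu : natural mortality rate (per year)
    gamma : rate at which complications are controlled (per year)
    nu : rate of becoming severely disabled (per year)
    incidence : new diabetes cases per year (persons/yr)
    """

    lambda_: float = 0.85
    delta: float = 0.05
    mu: float = 0.02
    gamma: float = 0.5
    nu: float = 0.05
    incidence: float = 6e6

    def __post_init__(self) -> None:
        for name in ("lambda_", "delta", "mu", "gamma", "nu", "incidence"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"parameter {name!r} must be finite and >= 0, got {value}")
        if self.mu == 0 and self.delta == 0 and self.nu == 0:
            raise ValueError("at least one of mu, delta, nu must be positive (no outflow)")
        # theta > 0 follows from the outflow condition above.

    @property
    def theta(self) -> float:
        """Total outflow rate from the complications compartment."""
        return self.gamma + self.mu + self.nu + self.delta

    @property
    def rho(self) -> float:
        """Alias of ``lambda_`` used by the closed-form solution."""
        return self.lambda_

    def system_matrix(self) -> np.ndarray:
        """Constant Jacobian ``A`` of the (C, N) system."""
        return np.array(
            [
                [-(self.lambda_ + self.theta), self.lambda_],
                [-(self.nu + self.delta), -self.mu],
            ]
        )

    def forcing(self) -> np.ndarray:
        """Constant forcing ``b = (I, 2I)`` of the (C, N) system."""
        return np.array([self.incidence, 2.0 * self.incidence])

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {
            "lambda": self.lambda_,
            "delta": self.delta,
            "mu": self.mu,
            "gamma": self.gamma,
            "nu": self.nu,
            "incidence": self.incidence,
        }

    @classmethod
    def from_dict(cls, mapping: dict[str, float]) -> "ModelParameters":
        kwargs = dict(mapping)
        if "lambda" in kwargs:
            kwargs["lambda_"] = kwargs.pop("lambda")
        return cls(**kwargs)


@dataclass(frozen=True)
class State:
    """A (t, C, N) sample of the system.

    ``D = N - C`` is derived.  Numerical schemes may step outside the
    physically meaningful region; ``valid`` records (rather than forbids)
    whether ``0 <= C <= N`` holds.
    """

    t: float
    C: float
    N: float

    @property
    def D(self) -> float:
        return self.N - self.C

    @property
    def valid(self) -> bool:
        return self.C >= 0 and self.N >= self.C

    def as_array(self) -> np.ndarray:
        return np.array([self.C, self.N])


@dataclass(frozen=True)
class DerivedConstants:
    """Composite rates of the closed-form solution.

    ``theta = gamma + mu + nu + delta``; ``sigma = rho + theta + mu`` is the
    (negated) trace of the system matrix; ``beta = rho(nu+delta) + mu(rho+theta)``
    its determinant; ``alpha = 2 rho + mu``.  ``eta1 <= eta2`` are the modal
    decay rates, the roots of ``chi^2 - sigma chi + beta = 0``.
    """

    theta: float
    sigma: float
    beta: float
    alpha: float
    eta1: float
    eta2: float


@dataclass(frozen=True)
class Equilibrium:
    """Steady state of the model.

    ``variant="ode_consistent"`` is the exact root of the right-hand sides;
    ``variant="paper_formula"`` evaluates the closed-form critical-point
    expressions verbatim.  The two C* agree algebraically; the N* differ
    (the ode_consistent value is the one trajectories converge to).
    """

    C_star: float
    N_star: float
    variant: str

    def as_array(self) -> np.ndarray:
        return np.array([self.C_star, self.N_star])


def rhs(state: State, params: ModelParameters) -> tuple[float, float]:
    """Right-hand sides ``(dC/dt, dN/dt)`` in persons/year."""
    dC = params.incidence - (params.lambda_ + params.theta) * state.C + params.lambda_ * state.N
    dN = 2.0 * params.incidence - (params.nu + params.delta) * state.C - params.mu * state.N
    return dC, dN


def rhs_dc(D: float, C: float, params: ModelParameters) -> tuple[float, float]:
    """Right-hand sides ``(dD/dt, dC/dt)`` of the two-compartment form.

    Incidence enters both compartments (a share of new cases already carries
    complications at diagnosis), which makes ``dD/dt + dC/dt`` equal the
    ``dN/dt`` of :func:`rhs` with ``N = D + C``.
    """
    dD = params.incidence - (params.lambda_ + params.mu) * D + params.gamma * C
    dC = params.incidence + params.lambda_ * D - params.theta * C
    return dD, dC


def derived_constants(params: ModelParameters) -> DerivedConstants:
    """Composite rates and modal decay rates ``eta1 <= eta2``.

    Raises
    ------
    ComplexModesError
        If ``sigma^2 < 4 beta`` (complex spectrum; cannot occur for
        nonnegative rates, but guarded for robustness).
    """
    rho = params.rho
    theta = params.theta
    sigma = rho + theta + params.mu
    beta = rho * (params.nu + params.delta) + params.mu * (rho + theta)
    alpha = 2.0 * rho + params.mu
    radicand = sigma * sigma - 4.0 * beta
    if radicand < 0:
        raise ComplexModesError(
            f"complex modes: sigma^2 = {sigma**2:.6g} < 4 beta = {4 * beta:.6g}"
        )
    root = math.sqrt(radicand)
    return DerivedConstants(
        theta=theta,
        sigma=sigma,
        beta=beta,
        alpha=alpha,
        eta1=0.5 * (sigma - root),
        eta2=0.5 * (sigma + root),
    )


def equilibrium(params: ModelParameters, variant: str = "ode_consistent") -> Equilibrium:
    """Steady state ``(C*, N*)``.

    Raises
    ------
    SingularSystemError
        If ``beta = 0`` (singular system matrix, no unique equilibrium).
    """
    rho = params.rho
    theta = params.theta
    beta = rho * (params.nu + params.delta) + params.mu * (rho + theta)
    if beta == 0:
        raise SingularSystemError("beta = 0: system matrix is singular")
    if variant == "paper_formula":
        denom = rho * (params.nu + params.delta + params.mu) + params.mu * theta
        C_star = (2.0 * rho + params.mu) * params.incidence / denom
        N_star = (2.0 * (rho + theta) - (params.mu + params.delta)) * params.incidence / denom
        return Equilibrium(C_star=C_star, N_star=N_star, variant=variant)
    if variant == "ode_consistent":
        x = np.linalg.solve(params.system_matrix(), -params.forcing())
        return Equilibrium(C_star=float(x[0]), N_star=float(x[1]), variant=variant)
    raise ValueError(f"unknown equilibrium variant {variant!r}")


def initial_conditions(
    params: ModelParameters, offset_C: float = 500.0, offset_N: float = 500.0
) -> State:
    """Initial state at ``t = 0``: the (ode-consistent) equilibrium plus offsets."""
    eq = equilibrium(params, variant="ode_consistent")
    return State(t=0.0, C=eq.C_star + offset_C, N=eq.N_star + offset_N)
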