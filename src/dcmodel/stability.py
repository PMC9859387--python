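"""Linear stability analysis of the DC model.

The system matrix of the (C, N) dynamics has characteristic equation

    chi^2 + (lambda + theta + mu) chi + [lambda (nu + delta) + mu (lambda + theta)] = 0,

i.e. trace ``-(lambda+theta+mu)`` and determinant
``lambda(nu+delta) + mu(lambda+theta)``.  For any strictly positive
parameter set the trace is negative and the determinant positive, so the
equilibrium is an asymptotically stable node — complications dynamics always
relax to the steady state.  The classifier below covers the full phase-plane
taxonomy (node, saddle, proper/improper node, spiral, center) for arbitrary
eigenvalue pairs.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, replace

from .model import ModelParameters

__all__ = [
    "StabilityReport",
    "Classification",
    "characteristic",
    "eigenvalues",
    "classify",
    "analyze",
]


@dataclass(frozen=True)
class Classification:
    """Phase-plane verdict for an eigenvalue pair.

    ``nonstandard_label`` marks the center case, which classical theory calls
    (marginally) stable rather than asymptotically stable; the reported label
    keeps the taxonomy's wording with this annotation.
    """

    critical_point_type: str
    stability: str
    nonstandard_label: bool = False


@dataclass(frozen=True)
class StabilityReport:
    """Characteristic-equation coefficients, discriminant, and (optionally)
    eigenvalues plus classification."""

    trace_coeff: float  # linear coefficient: lambda + theta + mu (= -trace)
    det_coeff: float  # constant coefficient: the determinant
    discriminant: float
    chi1: complex | None = None
    chi2: complex | None = None
    classification: Classification | None = None


def characteristic(params: ModelParameters) -> StabilityReport:
    """Coefficients and discriminant of the characteristic equation."""
    trace_coeff = params.lambda_ + params.theta + params.mu
    det_coeff = params.lambda_ * (params.nu + params.delta) + params.mu * (
        params.lambda_ + params.theta
    )
    discriminant = trace_coeff * trace_coeff - 4.0 * det_coeff
    return StabilityReport(
        trace_coeff=trace_coeff, det_coeff=det_coeff, discriminant=discriminant
    )


def eigenvalues(report: StabilityReport) -> tuple[complex, complex]:
    """Roots of the characteristic equation; ``chi1 >= chi2`` when real."""
    p, disc = report.trace_coeff, report.discriminant
    if disc >= 0:
        root = math.sqrt(disc)
        return (-p + root) / 2.0, (-p - root) / 2.0
    root = cmath.sqrt(disc)
    return (-p + root) / 2.0, (-p - root) / 2.0


def classify(chi1: complex, chi2: complex, tol: float = 0.0) -> Classification:
    """Phase-plane type and stability of the eigenvalue pair.

    Real pairs map to nodes/saddles, complex pairs to spirals, pure imaginary
    pairs to a center.  ``tol`` treats tiny imaginary/real parts as zero.
    """
    im1, im2 = complex(chi1).imag, complex(chi2).imag
    re1, re2 = complex(chi1).real, complex(chi2).real
    if abs(im1) <= tol and abs(im2) <= tol:
        a, b = re1, re2
        if a == b:
            if a < 0:
                return Classification("proper_or_improper_node", "asymptotically_stable")
            if a > 0:
                return Classification("proper_or_improper_node", "unstable")
            return Classification("degenerate", "not_classified")
        if a > 0 and b > 0:
            return Classification("node", "unstable")
        if a < 0 and b < 0:
            return Classification("node", "asymptotically_stable")
        if a * b < 0:
            return Classification("saddle_point", "unstable")
        return Classification("degenerate", "not_classified")  # one zero eigenvalue
    if abs(re1) <= tol and abs(re2) <= tol:
        # The taxonomy labels a center "asymptotically stable"; classically it
        # is only marginally stable — flagged as a nonstandard label.
        return Classification("center", "asymptotically_stable", nonstandard_label=True)
    if re1 < 0 and re2 < 0:
        return Classification("spiral_point", "asymptotically_stable")
    return Classification("spiral_point", "unstable")


def analyze(params: ModelParameters) -> StabilityReport:
    """Full report: coefficients, discriminant, eigenvalues, classification."""
    report = characteristic(params)
    chi1, chi2 = eigenvalues(report)
    return replace(report, chi1=chi1, chi2=chi2, classification=classify(chi1, chi2))
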