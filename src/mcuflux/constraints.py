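"""Kinetic and thermodynamic constraints linking the barrier-model parameters.

Thermodynamic consistency of the Eyring-barrier formulation requires

* kinetic constraint:        k_in0·K_x0² = k_out0·K_e0²
  (ties the zero-potential constants so that the equilibrium constant of
  the overall translocation matches the Nernst ratio), and
* thermodynamic constraint:  α_e + α_x + β_e + β_x = 1
  (the electrical displacements of the two binding sites and the barrier
  span the whole membrane).

Case 1 assumes equal external/internal constants (K_e0 = K_x0, k_in0 =
k_out0), which satisfies the kinetic constraint automatically.  Case 2
leaves the internal constants distinct but is degenerate: the one-parameter
family K_x0 → m·K_x0, k_out0 → m²·k_out0 (m > 0) preserves both
constraints and leaves the flux essentially unchanged whenever
[Ca2+]_x ≪ K_x0, so m is not identifiable from uptake data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import Case, PreviousParams, Variant

__all__ = [
    "ConstraintReport",
    "constraint_residuals",
    "apply_case",
    "free_vector",
    "case2_family",
    "DEFAULT_TOLERANCE",
]

DEFAULT_TOLERANCE = 1e-9


@dataclass(frozen=True)
class ConstraintReport:
    """Relative residuals of the two consistency constraints."""

    kinetic_residual: float
    thermodynamic_residual: float
    tolerance: float = DEFAULT_TOLERANCE

    @property
    def satisfied(self) -> bool:
        return (
            self.kinetic_residual <= self.tolerance
            and self.thermodynamic_residual <= self.tolerance
        )


def constraint_residuals(
    params: PreviousParams, tolerance: float = DEFAULT_TOLERANCE
) -> ConstraintReport:
    """Evaluate both constraint residuals for a barrier-model parameter set.

    The kinetic residual is |k_in0·K_x0² − k_out0·K_e0²| relative to
    k_out0·K_e0²; the thermodynamic residual is
    |α_e + α_x + β_e + β_x − 1|.
    """
    lhs = params.k_in0 * params.K_x0**2
    rhs = params.k_out0 * params.K_e0**2
    kinetic = abs(lhs - rhs) / rhs
    thermo = abs(params.alpha_e + params.alpha_x + params.beta_e + params.beta_x - 1.0)
    return ConstraintReport(kinetic, thermo, tolerance)


def apply_case(
    params_free,
    case: Case,
    variant: Variant = Variant.MODEL1,
) -> PreviousParams:
    """Build a constraint-satisfying parameter set from a free vector.

    Case 1 free vector (length 4): ``(K0, k0, alpha, beta_e)`` with
    K_e0 = K_x0 = K0, k_in0 = k_out0 = k0, α_e = α_x = alpha, and
    β_x = 1 − 2·alpha − β_e imposed by the thermodynamic constraint.

    Case 2 free vector (length 5): ``(K_e0, k_in0, alpha, beta_e, m)``;
    the internal constants follow the m-family, K_x0 = m·K_e0 and
    k_out0 = m²·k_in0, which satisfies the kinetic constraint by
    construction.
    """
    case = Case(case)
    v = np.asarray(params_free, dtype=float)
    expected = 4 if case is Case.CASE1 else 5
    if v.shape != (expected,):
        raise ValueError(f"{case.value} free vector must have length {expected}, got {v.shape}")
    if case is Case.CASE1:
        K0, k0, alpha, beta_e = v
        return PreviousParams(
            k_in0=k0, k_out0=k0, K_e0=K0, K_x0=K0,
            alpha_e=alpha, alpha_x=alpha,
            beta_e=beta_e, beta_x=1.0 - 2.0 * alpha - beta_e,
            variant=variant, case=case,
        )
    K_e0, k_in0, alpha, beta_e, m = v
    if not m > 0:
        raise ValueError("m must be > 0")
    return PreviousParams(
        k_in0=k_in0, k_out0=m * m * k_in0, K_e0=K_e0, K_x0=m * K_e0,
        alpha_e=alpha, alpha_x=alpha,
        beta_e=beta_e, beta_x=1.0 - 2.0 * alpha - beta_e,
        variant=variant, case=case,
    )


def free_vector(params: PreviousParams) -> np.ndarray:
    """Inverse of :func:`apply_case` (round-trips exactly)."""
    if params.case is Case.CASE1:
        return np.array([params.K_e0, params.k_in0, params.alpha_e, params.beta_e])
    m = params.K_x0 / params.K_e0
    return np.array([params.K_e0, params.k_in0, params.alpha_e, params.beta_e, m])


def case2_family(params: PreviousParams, m: float) -> PreviousParams:
    """Apply the Case-2 scaling K_x0 → m·K_x0, k_out0 → m²·k_out0.

    A group action on the Case-2 parameter family: applying m1 then m2
    equals applying m1·m2.  Exposed as a diagnostic of the Case-2
    non-identifiability; it preserves both constraints and, under the
    experimental protocol conditions (matrix Ca2+ far below K_x0), changes
    the flux only negligibly.
    """
    if not m > 0:
        raise ValueError(f"m must be > 0, got {m}")
    if params.case is not Case.CASE2:
        raise ValueError("the m-family applies to Case 2 parameter sets")
    return params.replace(K_x0=m * params.K_x0, k_out0=m * m * params.k_out0)
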