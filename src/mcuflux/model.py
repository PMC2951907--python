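"""Uniporter flux expressions for both model formulations.

The mitochondrial Ca2+ uniporter is treated as a carrier that binds two
Ca2+ ions cooperatively on either membrane face and translocates the
doubly-occupied (charge +4) complex across the inner membrane.  Net influx
(positive into the matrix) is

    J = ( k_in·([Ca]_e/K_e)² − k_out·([Ca]_x/K_x)² ) / D

where D is the carrier-occupancy denominator (Model 1: quadratic saturation
terms only; Model 2: additional linear terms) and the ΔΨ dependence of the
rate and binding constants distinguishes the two formulations:

* previous (Eyring barrier): k_in = k_in0·e^{+4β_e φ}, k_out =
  k_out0·e^{−4β_x φ} with constant barrier displacements β_e, β_x;
* present (generalized GHK): k_in/out = k0·Φ(φ; nH)·e^{±2(1−2α)φ} with the
  even, smooth translocation factor Φ = [u/sinh u]^{nH}, u = 2φ/nH.

At nH = 1 the present rate constants reduce exactly to the standard
constant-field (GHK) coefficients for a charge-4 species.  Detailed balance
holds for every thermodynamically consistent parameter set: the net flux
vanishes when [Ca]_x/[Ca]_e = e^{2φ}.
"""

from __future__ import annotations

import numpy as np

from .params import PresentParams, PreviousParams, Variant
from .thermo import DEFAULT_THERMO, ThermoContext, reduced_potential

__all__ = [
    "phi_factor",
    "binding_constants_previous",
    "rate_constants_previous",
    "binding_constants_present",
    "rate_constants_present",
    "denominator",
    "flux_previous",
    "flux_present",
    "beta_effective",
    "e_factor",
]

# Below this |u| the closed form u/sinh(u) is evaluated by series to avoid
# 0/0; switch error is far below 1e-12.
_SERIES_U = 1e-4


def _log_u_over_sinh(u):
    """log(u / sinh u) for u >= 0, stable for both tiny and large u."""
    u = np.asarray(u, dtype=float)
    small = u < _SERIES_U
    us = np.where(small, u, 1.0)
    # series: log(u/sinh u) = -u^2/6 + 7 u^4/360 + O(u^6)
    series = -(us * us) / 6.0 + 7.0 * us**4 / 360.0
    ub = np.where(small, 1.0, u)
    # log(sinh u) = u + log1p(-e^{-2u}) - log 2, overflow-free
    direct = np.log(ub) - (ub + np.log1p(-np.exp(-2.0 * ub)) - np.log(2.0))
    return np.where(small, series, direct)


def phi_factor(phi, nH):
    """Even translocation factor Φ(φ; nH) of the generalized-GHK rates.

    Φ = [u/sinh(u)]^{nH} with u = 2φ/nH; Φ(0) = 1, Φ(φ) = Φ(−φ), smooth
    everywhere.  nH = 1 recovers the standard constant-field factor.
    """
    if not nH > 0:
        raise ValueError(f"nH must be > 0, got {nH}")
    phi = np.asarray(phi, dtype=float)
    u = 2.0 * np.abs(phi) / nH
    out = np.exp(nH * _log_u_over_sinh(u))
    return out if out.ndim else float(out)


def binding_constants_previous(params: PreviousParams, phi):
    """ΔΨ-dependent binding constants K_e, K_x (molar) of the barrier model."""
    phi = np.asarray(phi, dtype=float)
    K_e = params.K_e0 * np.exp(-2.0 * params.alpha_e * phi)
    K_x = params.K_x0 * np.exp(+2.0 * params.alpha_x * phi)
    return K_e, K_x


def rate_constants_previous(params: PreviousParams, phi):
    """ΔΨ-dependent translocation rate constants k_in, k_out (nmol/mg/s)."""
    phi = np.asarray(phi, dtype=float)
    k_in = params.k_in0 * np.exp(+4.0 * params.beta_e * phi)
    k_out = params.k_out0 * np.exp(-4.0 * params.beta_x * phi)
    return k_in, k_out


def binding_constants_present(params: PresentParams, phi):
    """Binding constants of the generalized-GHK model (symmetric sites)."""
    phi = np.asarray(phi, dtype=float)
    K_e = params.K0 * np.exp(-2.0 * params.alpha * phi)
    K_x = params.K0 * np.exp(+2.0 * params.alpha * phi)
    return K_e, K_x


def rate_constants_present(params: PresentParams, phi):
    """Generalized-GHK rate constants k_in, k_out sharing the even factor Φ.

    The antisymmetric exponent 2(1−2α)φ enforces detailed balance together
    with the ΔΨ-dependent binding constants; k_in(φ) = k_out(−φ).
    """
    phi = np.asarray(phi, dtype=float)
    f = phi_factor(phi, params.nH)
    expo = np.exp(2.0 * (1.0 - 2.0 * params.alpha) * phi)
    return params.k0 * f * expo, params.k0 * f / expo


def denominator(ca_e, ca_x, K_e, K_x, variant: Variant = Variant.MODEL1):
    """Carrier-occupancy denominator D (dimensionless, >= 1)."""
    K_e = np.asarray(K_e, dtype=float)
    K_x = np.asarray(K_x, dtype=float)
    if np.any(K_e <= 0) or np.any(K_x <= 0):
        raise ValueError("binding constants must be positive")
    re = np.asarray(ca_e, dtype=float) / K_e
    rx = np.asarray(ca_x, dtype=float) / K_x
    D = 1.0 + re * re + rx * rx
    if Variant(variant) is Variant.MODEL2:
        D = D + re + rx
    return D


def _check_conditions(ca_e, ca_x, dpsi_mV):
    ca_e = np.asarray(ca_e, dtype=float)
    ca_x = np.asarray(ca_x, dtype=float)
    dpsi = np.asarray(dpsi_mV, dtype=float)
    if np.any(ca_e <= 0) or np.any(ca_x <= 0):
        raise ValueError("concentrations must be positive")
    if not np.all(np.isfinite(dpsi)):
        raise ValueError("dpsi must be finite")
    return ca_e, ca_x, dpsi


def flux_previous(
    ca_e, ca_x, dpsi_mV, params: PreviousParams,
    thermo: ThermoContext = DEFAULT_THERMO,
):
    """Net uniporter Ca2+ influx (nmol/mg/s) under the Eyring-barrier model.

    Parameters
    ----------
    ca_e, ca_x
        External and matrix free Ca2+, molar (scalar or array).
    dpsi_mV
        Membrane potential Ψ_e − Ψ_x, mV.
    """
    ca_e, ca_x, dpsi = _check_conditions(ca_e, ca_x, dpsi_mV)
    phi = reduced_potential(dpsi, thermo)
    K_e, K_x = binding_constants_previous(params, phi)
    k_in, k_out = rate_constants_previous(params, phi)
    D = denominator(ca_e, ca_x, K_e, K_x, params.variant)
    out = (k_in * (ca_e / K_e) ** 2 - k_out * (ca_x / K_x) ** 2) / D
    return out if np.ndim(out) else float(out)


def flux_present(
    ca_e, ca_x, dpsi_mV, params: PresentParams,
    thermo: ThermoContext = DEFAULT_THERMO,
):
    """Net uniporter Ca2+ influx (nmol/mg/s) under the generalized-GHK model.

    Finite and smooth at ΔΨ = 0 (the removable singularity of Φ is handled
    by a series branch)."""
    ca_e, ca_x, dpsi = _check_conditions(ca_e, ca_x, dpsi_mV)
    phi = reduced_potential(dpsi, thermo)
    K_e, K_x = binding_constants_present(params, phi)
    k_in, k_out = rate_constants_present(params, phi)
    D = denominator(ca_e, ca_x, K_e, K_x, params.variant)
    out = (k_in * (ca_e / K_e) ** 2 - k_out * (ca_x / K_x) ** 2) / D
    return out if np.ndim(out) else float(out)


def flux(ca_e, ca_x, dpsi_mV, params, thermo: ThermoContext = DEFAULT_THERMO):
    """Dispatch on parameter type to the matching flux expression."""
    if isinstance(params, PresentParams):
        return flux_present(ca_e, ca_x, dpsi_mV, params, thermo)
    if isinstance(params, PreviousParams):
        return flux_previous(ca_e, ca_x, dpsi_mV, params, thermo)
    raise TypeError(f"unsupported parameter type {type(params)!r}")


def beta_effective(phi, nH):
    """Voltage-dependent barrier displacements (β_e, β_x) of the present model.

    Obtained by matching the generalized-GHK rate constants to the
    Eyring-barrier form with α = 0:

        β_e(φ) = 1/2 + ln Φ(φ; nH) / (4φ),   β_x(φ) = 1 − β_e(φ).

    Both are smooth through φ = 0 (β_e(0) = β_x(0) = 1/2) and satisfy
    β_e + β_x = 1 identically.
    """
    if not nH > 0:
        raise ValueError(f"nH must be > 0, got {nH}")
    phi = np.asarray(phi, dtype=float)
    small = np.abs(phi) < _SERIES_U
    phis = np.where(small, 1.0, phi)
    u = 2.0 * np.abs(phis) / nH
    direct = nH * _log_u_over_sinh(u) / (4.0 * np.abs(phis)) * np.sign(phis)
    # odd series of ln Φ/(4φ): −φ/(6 nH) + 7 φ³/(90 nH³) + O(φ^5)
    series = -phi / (6.0 * nH) + 7.0 * phi**3 / (90.0 * nH**3)
    corr = np.where(small, series, direct)
    beta_e = 0.5 + corr
    beta_x = 0.5 - corr
    if beta_e.ndim:
        return beta_e, beta_x
    return float(beta_e), float(beta_x)


def e_factor(phi, params, formulation: str):
    """Even, zero-potential-normalized ΔΨ factor E of the flux expression.

    Writing k_in = k_in0·E(φ)·e^{+2φ} and k_out = k_out0·E(φ)·e^{−2φ}
    (α = 0), the present model gives E = Φ(φ; nH): smooth and
    differentiable at φ = 0.  For the previous model the same even
    decomposition of the constant-β rate constants gives

        E(φ) = exp((4β_e − 2)·φ) for φ ≥ 0,  exp((4β_x − 2)·φ) for φ < 0,

    i.e. exp(−(2 − 4β_e)|φ|) when β_e + β_x = 1: continuous and even but kinked
    (non-differentiable) at φ = 0.  Evaluated as published, for diagnostic
    comparison only.
    """
    phi = np.asarray(phi, dtype=float)
    if formulation == "present":
        if not isinstance(params, PresentParams):
            raise TypeError("present formulation requires PresentParams")
        out = phi_factor(phi, params.nH)
    elif formulation == "previous":
        if not isinstance(params, PreviousParams):
            raise TypeError("previous formulation requires PreviousParams")
        out = np.where(
            phi >= 0,
            np.exp((4.0 * params.beta_e - 2.0) * phi),
            np.exp((4.0 * params.beta_x - 2.0) * phi),
        )
    else:
        raise ValueError(f"unknown formulation {formulation!r}; use 'previous' or 'present'")
    return out if np.ndim(out) else float(out)
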