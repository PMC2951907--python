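"""Independent scalar transcription of the uniporter flux expressions.

This module was written before (and independently of) the vectorized
implementation in :mod:`mcuflux.model`.  It uses plain ``math`` scalar
arithmetic and deliberately different algebraic arrangements of the same
expressions (e.g. the translocation factor is written in its
``2u·e^{-u}/(1-e^{-2u})`` form rather than ``u/sinh(u)``), so that sign or
factor transcription errors in the main implementation cannot cancel here.

It is used only as a cross-check oracle in the test suite.
"""

import math

F = 96485.0      # C/mol
R = 8.314        # J/(mol K)
T_DEFAULT = 298.15


def reduced_potential(dpsi_mV, temperature=T_DEFAULT):
    return F * (dpsi_mV * 1e-3) / (R * temperature)


def ghk_constant_field_in(k0, phi):
    """Constant-field (standard GHK) influx coefficient for the charge-4
    uniporter:2Ca complex, normalized so k_in(0) = k0."""
    z = 4.0
    if phi == 0.0:
        return k0
    return k0 * z * phi / (1.0 - math.exp(-z * phi))


def ghk_constant_field_out(k0, phi):
    z = 4.0
    if phi == 0.0:
        return k0
    return k0 * z * phi / (math.exp(z * phi) - 1.0)


def translocation_factor(phi, nH):
    """Even factor of the generalized-GHK rate constants, normalized to 1
    at zero potential:  [u / sinh(u)]^nH with u = 2*phi/nH, written here as
    [2u e^{-u} / (1 - e^{-2u})]^nH for u > 0."""
    u = 2.0 * abs(phi) / nH
    if u < 1e-8:
        base = 1.0 - u * u / 6.0
    else:
        base = 2.0 * u * math.exp(-u) / (1.0 - math.exp(-2.0 * u))
    return base ** nH


def rate_constants_present(k0, nH, alpha, phi):
    f = translocation_factor(phi, nH)
    e = math.exp(2.0 * (1.0 - 2.0 * alpha) * phi)
    return k0 * f * e, k0 * f / e


def binding_constants_present(K0, alpha, phi):
    return K0 * math.exp(-2.0 * alpha * phi), K0 * math.exp(2.0 * alpha * phi)


def rate_constants_previous(k_in0, k_out0, beta_e, beta_x, phi):
    return k_in0 * math.exp(4.0 * beta_e * phi), k_out0 * math.exp(-4.0 * beta_x * phi)


def binding_constants_previous(K_e0, K_x0, alpha_e, alpha_x, phi):
    return K_e0 * math.exp(-2.0 * alpha_e * phi), K_x0 * math.exp(2.0 * alpha_x * phi)


def denominator(ca_e, ca_x, K_e, K_x, variant):
    re = ca_e / K_e
    rx = ca_x / K_x
    d = 1.0 + re * re + rx * rx
    if variant == "model2":
        d += re + rx
    return d


def flux_previous(ca_e, ca_x, dpsi_mV, k_in0, k_out0, K_e0, K_x0,
                  alpha_e, alpha_x, beta_e, beta_x, variant="model1",
                  temperature=T_DEFAULT):
    phi = reduced_potential(dpsi_mV, temperature)
    K_e, K_x = binding_constants_previous(K_e0, K_x0, alpha_e, alpha_x, phi)
    k_in, k_out = rate_constants_previous(k_in0, k_out0, beta_e, beta_x, phi)
    D = denominator(ca_e, ca_x, K_e, K_x, variant)
    return (k_in * (ca_e / K_e) ** 2 - k_out * (ca_x / K_x) ** 2) / D


def flux_present(ca_e, ca_x, dpsi_mV, k0, K0, nH, alpha=0.0, variant="model1",
                 temperature=T_DEFAULT):
    phi = reduced_potential(dpsi_mV, temperature)
    K_e, K_x = binding_constants_present(K0, alpha, phi)
    k_in, k_out = rate_constants_present(k0, nH, alpha, phi)
    D = denominator(ca_e, ca_x, K_e, K_x, variant)
    return (k_in * (ca_e / K_e) ** 2 - k_out * (ca_x / K_x) ** 2) / D


def beta_effective(phi, nH):
    """Barrier-displacement functions of the generalized-GHK model,
    beta_e = 1/2 + ln(Phi)/(4 phi), via the flux-expression comparison."""
    if abs(phi) < 1e-6:
        corr = -phi / (6.0 * nH)
    else:
        corr = math.log(translocation_factor(phi, nH)) / (4.0 * phi)
    return 0.5 + corr, 0.5 - corr
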