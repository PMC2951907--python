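"""Thermodynamic context: physical constants and the reduced membrane potential.

The inner-mitochondrial-membrane potential is defined outside-minus-inside,
ΔΨ = Ψ_e − Ψ_x, so energized mitochondria sit near +190 mV.  All voltage
dependence in the flux models enters through the dimensionless reduced
potential φ = F·ΔΨ/(R·T).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ThermoContext", "DEFAULT_THERMO", "reduced_potential", "equilibrium_ratio"]

#: Valence of the transported ion (Ca2+).
CA_VALENCE = 2


@dataclass(frozen=True)
class ThermoContext:
    """Physical constants used to convert ΔΨ (mV) to the reduced potential.

    Parameters
    ----------
    faraday_constant
        Faraday constant, C/mol.
    gas_constant
        Molar gas constant, J/(mol K).
    temperature
        Absolute temperature, K.  Not reported with the original kinetic
        data; the default corresponds to 25 °C.
    """

    faraday_constant: float = 96485.0
    gas_constant: float = 8.314
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        if not (self.faraday_constant > 0 and self.gas_constant > 0):
            raise ValueError("physical constants must be positive")


DEFAULT_THERMO = ThermoContext()


def reduced_potential(dpsi_mV, thermo: ThermoContext = DEFAULT_THERMO):
    """Dimensionless reduced potential φ = F·ΔΨ/(R·T).

    Parameters
    ----------
    dpsi_mV
        Membrane potential ΔΨ = Ψ_e − Ψ_x in millivolts (scalar or array).
    thermo
        Physical-constant context.

    Returns
    -------
    float or ndarray
        φ, linear in ΔΨ with φ(0) = 0.
    """
    dpsi = np.asarray(dpsi_mV, dtype=float)
    if not np.all(np.isfinite(dpsi)):
        raise ValueError("dpsi must be finite")
    phi = thermo.faraday_constant * (dpsi * 1e-3) / (
        thermo.gas_constant * thermo.temperature
    )
    return phi if phi.ndim else float(phi)


def equilibrium_ratio(phi):
    """Matrix-to-external Ca2+ concentration ratio at electrochemical
    equilibrium, exp(z·φ) with z = 2.

    At this ratio the net uniporter flux vanishes for any thermodynamically
    consistent parameter set (detailed balance).
    """
    phi = np.asarray(phi, dtype=float)
    out = np.exp(CA_VALENCE * phi)
    return out if out.ndim else float(out)
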