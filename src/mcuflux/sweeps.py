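"""Simulation sweeps: matrix-Ca2+ robustness envelopes, ΔΨ/[Ca2+]_e flux
families, and the voltage-dependence diagnostic curves.

These reproduce the three kinds of simulation analysis used to compare the
two formulations: how much predicted uptake moves when the (experimentally
unknown) matrix Ca2+ is varied over its physiological 100–500 nM range;
flux surfaces over external Ca2+ and ΔΨ; and the barrier-displacement
functions β_e(ΔΨ), β_x(ΔΨ) together with the even voltage factor E(ΔΨ) of
each formulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import beta_effective, e_factor, flux
from .params import PresentParams, PreviousParams
from .protocols import ProtocolSpec
from .thermo import DEFAULT_THERMO, ThermoContext, reduced_potential

__all__ = ["SweepResult", "matrix_ca_envelope", "dpsi_family", "beta_and_e_curves"]


@dataclass(frozen=True)
class SweepResult:
    """Tidy gridded sweep output (one row per grid point)."""

    kind: str
    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            for key in sorted(self.metadata):
                fh.write(f"# {key}: {self.metadata[key]}\n")
            self.frame.to_csv(fh, index=False, float_format="%.10g")


def matrix_ca_envelope(
    params,
    spec: ProtocolSpec,
    ca_x_range: tuple[float, float] = (100e-9, 500e-9),
    n_ca_x: int = 17,
    thermo: ThermoContext = DEFAULT_THERMO,
) -> SweepResult:
    """Min/max flux envelope across matrix Ca2+ for one protocol.

    For every protocol condition, the flux is evaluated on ``n_ca_x``
    log-spaced matrix-Ca2+ values spanning ``ca_x_range`` plus the 250 nM
    reference.  The result carries per-condition ``flux_min``, ``flux_max``
    and ``flux_ref`` columns and a scalar robustness metric

        max over conditions of (flux_max − flux_min) / flux_ref,

    the executable form of "(in)sensitive to variation in matrix [Ca2+]".
    """
    lo, hi = ca_x_range
    if not (0 < lo < hi):
        raise ValueError("ca_x_range must be positive and increasing")
    ca_x_grid = np.geomspace(lo, hi, n_ca_x)
    cond = spec.conditions()
    ca_e = cond["ca_e"].to_numpy()
    dpsi = cond["dpsi"].to_numpy()
    fluxes = np.stack(
        [flux(ca_e, np.full_like(ca_e, cx), dpsi, params, thermo) for cx in ca_x_grid]
    )
    ref = flux(ca_e, np.full_like(ca_e, spec.ca_x), dpsi, params, thermo)
    frame = pd.DataFrame(
        {
            "ca_e_uM": ca_e * 1e6,
            "dpsi_mV": dpsi,
            "flux_min": fluxes.min(axis=0),
            "flux_max": fluxes.max(axis=0),
            "flux_ref": ref,
        }
    )
    metric = float(np.max((frame["flux_max"] - frame["flux_min"]) / frame["flux_ref"]))
    return SweepResult(
        kind="matrix_ca_envelope",
        frame=frame,
        metadata={
            "protocol_id": spec.protocol_id,
            "ca_x_range_nM": f"{lo * 1e9:g}-{hi * 1e9:g}",
            "n_ca_x": n_ca_x,
            "robustness_metric": metric,
            "params": repr(params),
        },
    )


def dpsi_family(
    params,
    ca_e_grid=None,
    dpsi_grid=None,
    ca_x: float = 250e-9,
    thermo: ThermoContext = DEFAULT_THERMO,
) -> SweepResult:
    """Flux surface over (external Ca2+, ΔΨ) at fixed matrix Ca2+.

    Defaults cover external Ca2+ 10–150 µM and ΔΨ 100–210 mV with 50
    points per axis.  Values are pointwise flux evaluations, no
    interpolation.
    """
    ca_e_grid = np.asarray(
        np.geomspace(10e-6, 150e-6, 50) if ca_e_grid is None else ca_e_grid, dtype=float
    )
    dpsi_grid = np.asarray(
        np.linspace(100.0, 210.0, 50) if dpsi_grid is None else dpsi_grid, dtype=float
    )
    CE, DP = np.meshgrid(ca_e_grid, dpsi_grid, indexing="ij")
    J = flux(CE.ravel(), np.full(CE.size, ca_x), DP.ravel(), params, thermo)
    frame = pd.DataFrame(
        {"ca_e_uM": CE.ravel() * 1e6, "dpsi_mV": DP.ravel(), "flux_nmol_mg_s": J}
    )
    return SweepResult(
        kind="dpsi_family",
        frame=frame,
        metadata={"ca_x_nM": ca_x * 1e9, "params": repr(params)},
    )


def beta_and_e_curves(
    present: PresentParams,
    previous: PreviousParams,
    dpsi_grid=None,
    thermo: ThermoContext = DEFAULT_THERMO,
) -> SweepResult:
    """β_e(ΔΨ), β_x(ΔΨ) and the even voltage factor E(ΔΨ), both formulations.

    The generalized-GHK curves are smooth through ΔΨ = 0; the barrier-model
    β's are the published constants for ΔΨ > 0, swapping across 0 under the
    mirrored even-factor decomposition, which makes E_previous kinked at 0.
    The grid must straddle (and include) ΔΨ = 0 so the contrast is visible.
    """
    dpsi = np.asarray(
        np.linspace(-200.0, 200.0, 201) if dpsi_grid is None else dpsi_grid, dtype=float
    )
    if not (dpsi.min() < 0 < dpsi.max()):
        raise ValueError("dpsi_grid should span negative and positive potentials")
    phi = reduced_potential(dpsi, thermo)
    be, bx = beta_effective(phi, present.nH)
    e_pres = e_factor(phi, present, "present")
    e_prev = e_factor(phi, previous, "previous")
    be_prev = np.where(phi >= 0, previous.beta_e, previous.beta_x)
    bx_prev = np.where(phi >= 0, previous.beta_x, previous.beta_e)
    frame = pd.DataFrame(
        {
            "dpsi_mV": dpsi,
            "beta_e_present": be,
            "beta_x_present": bx,
            "beta_e_previous": be_prev,
            "beta_x_previous": bx_prev,
            "E_present": e_pres,
            "E_previous": e_prev,
        }
    )
    return SweepResult(
        kind="beta_and_e_curves",
        frame=frame,
        metadata={"nH": present.nH, "beta_e_previous": previous.beta_e},
    )
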