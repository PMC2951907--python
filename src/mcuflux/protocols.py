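"""Synthetic kinetic datasets emulating the three classical uptake protocols.

The model was historically parameterized against three experiment families
measuring initial Ca2+ uptake rates in suspensions of energized
mitochondria:

* ``heart_ca_titration``  — rat-heart mitochondria, external Ca2+ varied,
  ΔΨ fixed at 190 mV (state-2 respiration);
* ``liver_ca_titration``  — rat-liver mitochondria, same design;
* ``liver_dpsi_titration`` — rat-liver mitochondria, ΔΨ varied (set
  experimentally via malonate titration) at external Ca2+ of 0.5, 1.0 and
  1.5 µM.

The original measurements were never deposited, so this module generates
synthetic stand-ins: model fluxes on protocol grids with multiplicative
Gaussian noise, fully reproducible from (seed, protocol, parameters).
Matrix Ca2+, unknown in the experiments, defaults to the 250 nM fitting
convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import flux
from .params import PresentParams, PreviousParams
from .thermo import DEFAULT_THERMO, ThermoContext

__all__ = [
    "PROTOCOL_IDS",
    "ProtocolSpec",
    "KineticDataset",
    "make_protocol",
    "generate_dataset",
    "read_dataset_csv",
]

PROTOCOL_IDS = ("heart_ca_titration", "liver_ca_titration", "liver_dpsi_titration")

#: CSV schema, in column order.  Concentration columns are unit-suffixed to
#: avoid the molar/µM ambiguity between the two published parameter tables.
CSV_COLUMNS = ["dataset_id", "protocol_id", "ca_e_uM", "ca_x_nM", "dpsi_mV", "rate_nmol_mg_s"]


def _default_ca_grid() -> np.ndarray:
    return np.geomspace(1e-6, 150e-6, 20)


def _default_dpsi_grid() -> np.ndarray:
    return np.linspace(60.0, 190.0, 15)


@dataclass(frozen=True)
class ProtocolSpec:
    """Conditions grid of one experimental protocol.

    Ca2+-titration protocols use ``ca_e_grid`` (molar) at ``dpsi_fixed``
    (mV); the ΔΨ-titration protocol uses ``dpsi_grid`` (mV) crossed with
    ``ca_e_levels`` (molar).  ``ca_x`` is the assumed matrix free Ca2+.
    """

    protocol_id: str
    ca_e_grid: tuple = ()
    dpsi_grid: tuple = ()
    dpsi_fixed: float = 190.0
    ca_e_levels: tuple = (0.5e-6, 1.0e-6, 1.5e-6)
    ca_x: float = 250e-9

    def __post_init__(self) -> None:
        if self.protocol_id not in PROTOCOL_IDS:
            raise ValueError(
                f"unknown protocol_id {self.protocol_id!r}; known: {PROTOCOL_IDS}"
            )
        for name in ("ca_e_grid", "dpsi_grid", "ca_e_levels"):
            object.__setattr__(self, name, tuple(float(x) for x in getattr(self, name)))
        if self.is_dpsi_titration:
            if len(self.dpsi_grid) == 0 or len(self.ca_e_levels) == 0:
                raise ValueError("ΔΨ titration needs a dpsi_grid and >= 1 ca_e level")
            grid = np.asarray(self.dpsi_grid)
        else:
            if len(self.ca_e_grid) == 0:
                raise ValueError("Ca titration needs a ca_e_grid")
            grid = np.asarray(self.ca_e_grid)
            if np.any(grid <= 0):
                raise ValueError("ca_e_grid must be positive")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grids must be strictly increasing")
        if np.any(np.asarray(self.ca_e_levels) <= 0) or self.ca_x <= 0:
            raise ValueError("concentrations must be positive")

    @property
    def is_dpsi_titration(self) -> bool:
        return self.protocol_id == "liver_dpsi_titration"

    def conditions(self) -> pd.DataFrame:
        """Flat table of (ca_e [M], ca_x [M], dpsi [mV]) rows on the grid."""
        if self.is_dpsi_titration:
            levels = np.repeat(self.ca_e_levels, len(self.dpsi_grid))
            dpsi = np.tile(self.dpsi_grid, len(self.ca_e_levels))
            ca_e = levels
        else:
            ca_e = np.asarray(self.ca_e_grid)
            dpsi = np.full(ca_e.shape, self.dpsi_fixed)
        return pd.DataFrame(
            {"ca_e": ca_e, "ca_x": np.full(ca_e.shape, self.ca_x), "dpsi": dpsi}
        )

    def replace(self, **changes) -> "ProtocolSpec":
        return replace(self, **changes)


def make_protocol(protocol_id: str, **overrides) -> ProtocolSpec:
    """Protocol spec with documented defaults.

    Ca titrations: 20 log-spaced external-Ca2+ points, 1–150 µM, at 190 mV.
    ΔΨ titration: 15 points, 60–190 mV, at each of 0.5/1.0/1.5 µM external
    Ca2+.  Matrix Ca2+ defaults to 250 nM everywhere.  Any field of
    :class:`ProtocolSpec` may be overridden by keyword.
    """
    if protocol_id not in PROTOCOL_IDS:
        raise ValueError(f"unknown protocol_id {protocol_id!r}; known: {PROTOCOL_IDS}")
    if protocol_id == "liver_dpsi_titration":
        base = dict(dpsi_grid=tuple(_default_dpsi_grid()))
    else:
        base = dict(ca_e_grid=tuple(_default_ca_grid()))
    base.update(overrides)
    return ProtocolSpec(protocol_id=protocol_id, **base)


@dataclass(frozen=True)
class KineticDataset:
    """One protocol's measured (or synthesized) initial uptake rates.

    ``frame`` holds one row per condition with columns ``ca_e`` (M),
    ``ca_x`` (M), ``dpsi`` (mV), ``rate`` (nmol/mg/s) and optionally
    ``rate_sd``.  ``provenance`` records how the rates were obtained.
    """

    dataset_id: str
    protocol: ProtocolSpec
    frame: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"ca_e", "ca_x", "dpsi", "rate"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"dataset frame missing columns {sorted(missing)}")
        if not np.all(np.isfinite(self.frame["rate"])):
            raise ValueError("rates must be finite")

    @property
    def rates(self) -> np.ndarray:
        return self.frame["rate"].to_numpy()

    @property
    def n(self) -> int:
        return len(self.frame)

    def to_csv(self, path_or_buf, provenance_header: bool = True) -> None:
        """Write the schema CSV (`ca_e_uM, ca_x_nM, dpsi_mV, rate_nmol_mg_s`).

        Provenance is emitted as ``# key: value`` comment lines above the
        header so that identical datasets serialize byte-identically.
        """
        out = pd.DataFrame(
            {
                "dataset_id": self.dataset_id,
                "protocol_id": self.protocol.protocol_id,
                "ca_e_uM": self.frame["ca_e"] * 1e6,
                "ca_x_nM": self.frame["ca_x"] * 1e9,
                "dpsi_mV": self.frame["dpsi"],
                "rate_nmol_mg_s": self.frame["rate"],
            }
        )
        if "rate_sd" in self.frame:
            out["rate_sd"] = self.frame["rate_sd"]
        buf = io.StringIO()
        if provenance_header:
            for key in sorted(self.provenance):
                buf.write(f"# {key}: {self.provenance[key]}\n")
        out.to_csv(buf, index=False, float_format="%.10g")
        text = buf.getvalue()
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)


def generate_dataset(
    params: "PresentParams | PreviousParams",
    spec: ProtocolSpec,
    noise_cv: float = 0.05,
    seed: int = 0,
    thermo: ThermoContext = DEFAULT_THERMO,
    dataset_id: str | None = None,
) -> KineticDataset:
    """Synthesize initial-rate data: model flux times multiplicative noise.

    rate_i = J(conditions_i) · (1 + noise_cv·ε_i) with ε_i i.i.d. standard
    normal from ``numpy.random.default_rng(seed)``.  ``noise_cv = 0``
    returns the exact model evaluations.
    """
    if noise_cv < 0:
        raise ValueError(f"noise_cv must be >= 0, got {noise_cv}")
    cond = spec.conditions()
    clean = flux(
        cond["ca_e"].to_numpy(), cond["ca_x"].to_numpy(), cond["dpsi"].to_numpy(),
        params, thermo,
    )
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(len(cond))
    cond = cond.assign(rate=clean * (1.0 + noise_cv * eps))
    provenance = {
        "source": "synthetic",
        "seed": seed,
        "noise_cv": noise_cv,
        "protocol_id": spec.protocol_id,
        "generating_params": repr(params),
    }
    return KineticDataset(
        dataset_id=dataset_id or spec.protocol_id,
        protocol=spec,
        frame=cond,
        provenance=provenance,
    )


def read_dataset_csv(path) -> KineticDataset:
    """Read a schema CSV (possibly user-supplied digitized data).

    Concentration columns must carry their unit suffixes; a missing or
    misnamed column raises a schema error naming it.
    """
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    protocol_id = str(frame["protocol_id"].iloc[0])
    ca_x = float(frame["ca_x_nM"].iloc[0]) * 1e-9
    data = pd.DataFrame(
        {
            "ca_e": frame["ca_e_uM"] * 1e-6,
            "ca_x": frame["ca_x_nM"] * 1e-9,
            "dpsi": frame["dpsi_mV"],
            "rate": frame["rate_nmol_mg_s"],
        }
    )
    if "rate_sd" in frame:
        data["rate_sd"] = frame["rate_sd"]
    if protocol_id == "liver_dpsi_titration":
        spec = ProtocolSpec(
            protocol_id=protocol_id,
            dpsi_grid=tuple(np.unique(data["dpsi"])),
            ca_e_levels=tuple(np.unique(data["ca_e"])),
            ca_x=ca_x,
        )
    else:
        spec = ProtocolSpec(
            protocol_id=protocol_id,
            ca_e_grid=tuple(np.unique(data["ca_e"])),
            dpsi_fixed=float(data["dpsi"].iloc[0]),
            ca_x=ca_x,
        )
    return KineticDataset(
        dataset_id=str(frame["dataset_id"].iloc[0]),
        protocol=spec,
        frame=data,
        provenance={"source": "user_csv", "path": str(path)},
    )
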