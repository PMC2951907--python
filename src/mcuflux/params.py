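"""Parameter containers for the two uniporter formulations.

Two generations of the model are supported:

* the *previous* (Eyring free-energy-barrier) formulation, with constant
  barrier-displacement parameters β_e, β_x and binding-site displacement
  parameters α_e, α_x;
* the *present* (generalized, nonlinear Goldman–Hodgkin–Katz) formulation,
  in which a single shape parameter nH replaces β_e and β_x, and the
  external/internal binding constants are tied (Case 1).

Concentrations are held internally in molar; rate constants in
nmol·mg⁻¹·s⁻¹ (the total uniporter density is absorbed into them).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from importlib import resources

__all__ = [
    "Variant",
    "Case",
    "PreviousParams",
    "PresentParams",
    "packaged_params",
    "available_params",
    "load_params_file",
]


class Variant(str, enum.Enum):
    """Cooperativity of the two Ca2+ binding steps."""

    MODEL1 = "model1"  # fully cooperative: quadratic saturation terms only
    MODEL2 = "model2"  # partial cooperativity: additional linear terms


class Case(str, enum.Enum):
    """Symmetry assumption on the external/internal binding constants."""

    CASE1 = "case1"  # K_e0 = K_x0 and k_in0 = k_out0
    CASE2 = "case2"  # distinct internal constants (m-family degenerate)


@dataclass(frozen=True)
class PreviousParams:
    """Eyring-barrier formulation parameters.

    ΔΨ dependence: K_e = K_e0·e^{−2α_e φ}, K_x = K_x0·e^{+2α_x φ},
    k_in = k_in0·e^{+4β_e φ}, k_out = k_out0·e^{−4β_x φ}.

    Thermodynamic consistency requires α_e + α_x + β_e + β_x = 1 and
    k_in0·K_x0² = k_out0·K_e0² (see :mod:`mcuflux.constraints`).
    """

    k_in0: float          # nmol/mg/s at ΔΨ = 0
    k_out0: float         # nmol/mg/s at ΔΨ = 0
    K_e0: float           # molar, external site at ΔΨ = 0
    K_x0: float           # molar, internal site at ΔΨ = 0
    alpha_e: float = 0.0
    alpha_x: float = 0.0
    beta_e: float = 0.113
    beta_x: float = 0.887
    variant: Variant = Variant.MODEL1
    case: Case = Case.CASE1

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant", Variant(self.variant))
        object.__setattr__(self, "case", Case(self.case))
        for name in ("k_in0", "k_out0", "K_e0", "K_x0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.case is Case.CASE1:
            if abs(self.K_e0 - self.K_x0) > 1e-12 * self.K_e0 or (
                abs(self.k_in0 - self.k_out0) > 1e-12 * self.k_in0
            ):
                raise ValueError("Case 1 requires K_e0 = K_x0 and k_in0 = k_out0")

    def replace(self, **changes) -> "PreviousParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class PresentParams:
    """Generalized-GHK formulation parameters (Case 1 by construction).

    ΔΨ dependence: k_in/out = k0·Φ(φ; nH)·e^{±2(1−2α)φ} with the even,
    smooth translocation factor Φ = [u/sinh u]^{nH}, u = 2φ/nH, Φ(0)=1;
    K_e = K0·e^{−2αφ}, K_x = K0·e^{+2αφ}.
    """

    k0: float             # nmol/mg/s, common zero-potential rate constant
    K0: float             # molar, common zero-potential binding constant
    nH: float = 2.65      # dimensionless shape parameter; nH = 1 is standard GHK
    alpha: float = 0.0    # dimensionless binding-site displacement, >= 0
    variant: Variant = Variant.MODEL1

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant", Variant(self.variant))
        if not self.k0 > 0:
            raise ValueError("k0 must be > 0")
        if not self.K0 > 0:
            raise ValueError("K0 must be > 0")
        if not self.nH > 0:
            raise ValueError("nH must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")

    def replace(self, **changes) -> "PresentParams":
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# Packaged parameter registry (transcribed published estimates)
# ---------------------------------------------------------------------------

_DATA_FILES = {
    "previous": "params_barrier.json",
    "present": "params_generalized.json",
}


def _load_json(name: str) -> dict:
    with resources.files("mcuflux.data").joinpath(name).open("r") as fh:
        return json.load(fh)


def _previous_from_entry(entry: dict, variant: str, case: str) -> PreviousParams:
    K_e0 = entry["K_e0_M"]
    K_x0 = entry.get("K_x0_M", K_e0)
    k_in0 = entry["k_in0_nmol_mg_s"]
    k_out0 = entry.get("k_out0_nmol_mg_s", k_in0)
    return PreviousParams(
        k_in0=k_in0, k_out0=k_out0, K_e0=K_e0, K_x0=K_x0,
        alpha_e=entry.get("alpha_e", 0.0), alpha_x=entry.get("alpha_x", 0.0),
        beta_e=entry["beta_e"], beta_x=entry["beta_x"],
        variant=Variant(variant), case=Case(case),
    )


def _present_from_entry(entry: dict, variant: str) -> PresentParams:
    return PresentParams(
        k0=entry["k0_nmol_mg_s"], K0=entry["K0_uM"] * 1e-6,
        nH=entry["nH"], alpha=entry.get("alpha", 0.0), variant=Variant(variant),
    )


def packaged_params(name: str):
    """Look up a packaged (published) parameter set by registry name.

    Names follow ``formulation/variant[/case]/dataset``, e.g.
    ``present/model1/liver``, ``present/model1/liver_dpsi``,
    ``previous/model1/case1/heart``.  ``present/.../liver`` refers to the
    liver Ca2+-titration preparation; ``liver_dpsi`` to the ΔΨ-titration
    preparation (rate constants differ between preparations).
    """
    parts = name.strip("/").split("/")
    if not parts or parts[0] not in _DATA_FILES:
        raise KeyError(f"unknown parameter set {name!r}; try one of {available_params()}")
    data = _load_json(_DATA_FILES[parts[0]])
    if parts[0] == "present":
        if len(parts) != 3:
            raise KeyError(f"present-formulation names are formulation/variant/dataset, got {name!r}")
        _, variant, dataset = parts
        try:
            return _present_from_entry(data[variant][dataset], variant)
        except KeyError as exc:
            raise KeyError(f"unknown parameter set {name!r}") from exc
    if len(parts) != 4:
        raise KeyError(f"previous-formulation names are formulation/variant/case/dataset, got {name!r}")
    _, variant, case, dataset = parts
    try:
        return _previous_from_entry(data[variant][case][dataset], variant, case)
    except KeyError as exc:
        raise KeyError(f"unknown parameter set {name!r}") from exc


def available_params() -> list[str]:
    """All registry names accepted by :func:`packaged_params`."""
    names: list[str] = []
    present = _load_json(_DATA_FILES["present"])
    for variant, entries in present.items():
        if variant.startswith("_"):
            continue
        names += [f"present/{variant}/{ds}" for ds in entries]
    previous = _load_json(_DATA_FILES["previous"])
    for variant, cases in previous.items():
        if variant.startswith("_"):
            continue
        for case, entries in cases.items():
            names += [f"previous/{variant}/{case}/{ds}" for ds in entries]
    return sorted(names)


def load_params_file(path) -> "PreviousParams | PresentParams":
    """Load a single parameter set from a user JSON file.

    The file carries a ``formulation`` key (``previous`` | ``present``) plus
    the unit-suffixed fields used by the packaged files
    (``K0_uM``/``K_e0_M``, ``k0_nmol_mg_s``/``k_in0_nmol_mg_s``, ...).
    """
    with open(path) as fh:
        entry = json.load(fh)
    formulation = entry.get("formulation")
    if formulation == "present":
        return _present_from_entry(entry, entry.get("variant", "model1"))
    if formulation == "previous":
        return _previous_from_entry(
            entry, entry.get("variant", "model1"), entry.get("case", "case1")
        )
    raise ValueError(f"{path}: 'formulation' must be 'previous' or 'present'")
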