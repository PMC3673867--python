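"""Electrochemical post-processing of flux solutions.

Converts electron fluxes (mmol e⁻/gDW/h) to specific current (A/gDW),
computes coulombic efficiency against acetate as the sole substrate
(8 mol e⁻ per mol acetate from full oxidation,
CH₃COOH + 2 H₂O → 2 CO₂ + 8 H⁺ + 8 e⁻), standard-cell EMF from formal
potentials at pH 7, and the resulting theoretical power ceiling.  Ohmic,
concentration-polarization and kinetic losses are deliberately outside the
model: every figure here is an upper bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

#: Exact conversion ratio: (96485 C/mol) / (1000 mmol/mol × 3600 s/h),
#: i.e. 0.0268014 A/gDW per mmol e⁻/gDW/h.
FARADAY = 96485.0
FLUX_TO_AMPERE = FARADAY / 3.6e6


@dataclass(frozen=True)
class ElectroConstants:
    """Physical constants and formal potentials (pH 7) used throughout.

    ``MET_anode`` is the NAD⁺/NADH couple, ``DET_anode`` the cytochrome-c
    Fe³⁺/Fe²⁺ couple, ``cathode`` the O₂/H₂O couple; volts.
    """

    faraday: float = FARADAY
    electrons_per_acetate: int = 8
    electrons_per_transfer_cycle: int = 2
    potentials: Mapping[str, float] = field(
        default_factory=lambda: MappingProxyType(
            {"MET_anode": -0.320, "DET_anode": 0.254, "cathode": 0.51}
        )
    )


DEFAULT_CONSTANTS = ElectroConstants()


@dataclass
class ModeSummary:
    """A Table-style summary row for one operating condition."""

    mode: str
    growth: float  # 1/h
    electron_flux: float  # mmol e-/gDW/h
    amperage: float  # A/gDW
    ce_percent: float  # %
    power: float  # W/gDW


def flux_to_current(electron_flux: float) -> float:
    """Specific current (A/gDW) from an electron flux (mmol e⁻/gDW/h)."""
    if electron_flux < 0:
        raise ValueError(f"electron flux must be >= 0, got {electron_flux}")
    return electron_flux * FLUX_TO_AMPERE


def current_to_flux(amperage: float) -> float:
    """Inverse of :func:`flux_to_current`."""
    return amperage / FLUX_TO_AMPERE


def coulombic_efficiency(
    electron_flux: float,
    acetate_uptake: float,
    constants: ElectroConstants = DEFAULT_CONSTANTS,
) -> float:
    """Percent of substrate electrons recovered as current.

    ``CE% = 100 × electron_flux / (8 × acetate_uptake)`` with acetate as the
    sole substrate.
    """
    if acetate_uptake <= 0:
        raise ValueError("coulombic efficiency is undefined at zero acetate uptake")
    return 100.0 * electron_flux / (constants.electrons_per_acetate * acetate_uptake)


def cell_emf(
    mode: str,
    constants: ElectroConstants = DEFAULT_CONSTANTS,
    per_channel: bool = False,
):
    """Standard cell potential ΔE°′ = E°′(cathode) − E°′(anode), volts.

    MET uses the NAD⁺/NADH anode couple (0.83 V against the O₂ cathode) and
    DET the cytochrome-c couple (0.256 V).  For MIXED the convention is the
    MET couple applied to the total current — the voltage window a combined
    circuit would have to operate at; ``per_channel=True`` instead returns
    ``{"DET": ..., "MET": ...}`` for channel-resolved power accounting.
    """
    mode = mode.upper()
    if mode not in ("DET", "MET", "MIXED"):
        raise ValueError(f"unknown mode {mode!r}")
    cathode = constants.potentials["cathode"]
    emf = {
        "MET": cathode - constants.potentials["MET_anode"],
        "DET": cathode - constants.potentials["DET_anode"],
    }
    if per_channel:
        if mode != "MIXED":
            raise ValueError("per_channel EMF only applies to MIXED mode")
        return dict(emf)
    return emf["MET"] if mode in ("MET", "MIXED") else emf["DET"]


def power_output(
    amperage: float, mode: str, constants: ElectroConstants = DEFAULT_CONSTANTS
) -> float:
    """Theoretical power ceiling (W/gDW): amperage × cell EMF."""
    if amperage < 0:
        raise ValueError(f"amperage must be >= 0, got {amperage}")
    return amperage * cell_emf(mode, constants)


def mixed_power_per_channel(
    amperage_det: float,
    amperage_met: float,
    constants: ElectroConstants = DEFAULT_CONSTANTS,
) -> float:
    """Channel-resolved MIXED power: each current at its own couple's EMF."""
    emf = cell_emf("MIXED", constants, per_channel=True)
    return amperage_det * emf["DET"] + amperage_met * emf["MET"]


def biofilm_to_specific(
    per_area: float, protein_density: float, protein_fraction: float
) -> float:
    """Convert an areal figure (A/m² or W/m²) to a biomass-specific one.

    Divides by the areal dry-weight density
    ``protein_density / protein_fraction`` (g dry weight per m²), e.g. a
    biofilm at 0.571 g protein/m² with 46% protein content carries
    1.241 gDW/m².
    """
    if protein_density <= 0:
        raise ValueError("protein density must be > 0")
    if not (0 < protein_fraction <= 1):
        raise ValueError("protein fraction must be in (0, 1]")
    if per_area < 0:
        raise ValueError("areal quantity must be >= 0")
    return per_area / (protein_density / protein_fraction)


def mode_summary(
    mode: str,
    growth: float,
    electron_flux: float,
    acetate_uptake: float,
    constants: ElectroConstants = DEFAULT_CONSTANTS,
) -> ModeSummary:
    """Assemble amperage, CE and power for one condition."""
    amperage = flux_to_current(electron_flux)
    return ModeSummary(
        mode=mode.upper(),
        growth=growth,
        electron_flux=electron_flux,
        amperage=amperage,
        ce_percent=coulombic_efficiency(electron_flux, acetate_uptake, constants),
        power=power_output(amperage, mode, constants),
    )
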