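"""Convert literature-style culture observations to per-cell steady-state fluxes.

Model predictions are per-cell rates (umol/cell/s); published experiments
report either exponential growth on the pathway substrate or a volumetric
product titer.  The two converters here put those observations on the model's
axis so they can be compared with predicted fluxes.

Conventions: the growth conversion uses the mass accumulation rate
``cell_mass / doubling_time`` (no ln 2 factor) and a single mass fraction of
pathway flux routed to growth; both conversions are exactly linear in their
observation magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidParameterError

__all__ = [
    "GrowthObservation",
    "TiterObservation",
    "flux_from_growth",
    "flux_from_titer",
]

#: Molar mass of 1,2-propanediol (g/mol), for growth-on-substrate conversions.
MOLAR_MASS_12PD = 76.09


@dataclass(frozen=True)
class GrowthObservation:
    """Exponential growth sustained by flux through the pathway.

    doubling_time : s
    cell_mass : g (dry-ish single-cell mass, ~0.3 pg for an enteric bacterium)
    flux_mass_fraction_to_growth : fraction of pathway flux (by mass)
        convertible to biomass, in (0, 1]
    substrate_molar_mass : g/mol
    """

    doubling_time: float
    cell_mass: float
    flux_mass_fraction_to_growth: float
    substrate_molar_mass: float

    def __post_init__(self):
        if self.doubling_time <= 0:
            raise InvalidParameterError("doubling_time must be > 0")
        if self.cell_mass <= 0:
            raise InvalidParameterError("cell_mass must be > 0")
        if not (0 < self.flux_mass_fraction_to_growth <= 1):
            raise InvalidParameterError(
                "flux_mass_fraction_to_growth must be in (0, 1]"
            )
        if self.substrate_molar_mass <= 0:
            raise InvalidParameterError("substrate_molar_mass must be > 0")


@dataclass(frozen=True)
class TiterObservation:
    """Volumetric product titer accumulated by a culture.

    titer : uM
    duration : s (production assumed constant over this window)
    cell_density : cells/cm^3 (2 OD ~ 2e9 cells/mL = 2e9 cells/cm^3)
    """

    titer: float
    duration: float
    cell_density: float

    def __post_init__(self):
        if self.titer < 0:
            raise InvalidParameterError("titer must be >= 0")
        if self.duration <= 0:
            raise InvalidParameterError("duration must be > 0")
        if self.cell_density <= 0:
            raise InvalidParameterError("cell_density must be > 0")


def flux_from_growth(obs: GrowthObservation) -> float:
    """Per-cell pathway flux (umol/cell/s) sustaining an observed growth rate.

    flux = (cell_mass / doubling_time) / fraction / molar_mass, converted
    from mol/cell/s to umol/cell/s.
    """
    mol_per_s = (
        obs.cell_mass
        / obs.doubling_time
        / obs.flux_mass_fraction_to_growth
        / obs.substrate_molar_mass
    )
    return mol_per_s * 1.0e6


def flux_from_titer(obs: TiterObservation) -> float:
    """Per-cell pathway flux (umol/cell/s) behind an observed product titer.

    flux = titer / (duration * cell_density); uM cm^3 = 1e-3 umol.
    """
    return obs.titer / (obs.duration * obs.cell_density) * 1.0e-3
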