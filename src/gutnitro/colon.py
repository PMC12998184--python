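"""Whole-colon nitrite detoxification capacity.

Scales measured specific activities (umol g_DW^-1 h^-1) up to the organ:
taxon cell counts per g dry stool follow from relative abundance times the
total bacterial count, biomass follows via the average per-cell dry mass,
stool dry mass from wet volume, density and water content, and the product
chain gives the total colonic activity. A nitrite bolus divided by that
activity gives the detoxification time (zero-order capacity argument). The
same chain run backwards turns a community activity into an implied
abundance of the dominant degrader.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "StoolPhysiology",
    "TaxonProfile",
    "ColonActivityResult",
    "BolusScenario",
    "colon_dry_mass",
    "taxon_cells_per_gds",
    "biomass_per_gds",
    "activity_chain",
    "bolus_amount",
    "detox_time",
    "back_estimate_abundance",
    "mixture_activity",
]


@dataclass(frozen=True)
class StoolPhysiology:
    """Stool and colon constants tying cell counts to organ-scale biomass."""

    cells_per_g_dry_stool: float = 3.23e11
    wet_volume_ml: float = 400.0
    density_g_per_ml: float = 1.04
    water_fraction: float = 0.75
    per_cell_dw: float = 2.52e-13  # g

    def __post_init__(self) -> None:
        if not 0 < self.water_fraction < 1:
            raise ValueError("water_fraction must lie in (0, 1)")
        if min(
            self.cells_per_g_dry_stool,
            self.wet_volume_ml,
            self.density_g_per_ml,
            self.per_cell_dw,
        ) <= 0:
            raise ValueError("physiology constants must be > 0")


@dataclass(frozen=True)
class TaxonProfile:
    """A taxon's share of the community and its measured specific activity."""

    species: str
    abundance: float  # fraction of cells, e.g. 0.008
    specific_activity: float  # umol g_DW^-1 h^-1

    def __post_init__(self) -> None:
        if not 0 <= self.abundance <= 1:
            raise ValueError("abundance must lie in [0, 1]")
        if self.specific_activity < 0:
            raise ValueError("specific_activity must be >= 0")


@dataclass(frozen=True)
class BolusScenario:
    conc_uM: float = 50.0
    volume_ml: float = 400.0

    def __post_init__(self) -> None:
        if self.conc_uM < 0 or self.volume_ml <= 0:
            raise ValueError("bolus concentration must be >= 0 and volume > 0")


@dataclass(frozen=True)
class ColonActivityResult:
    """All intermediates of the organ-scale activity chain, exposed."""

    species: str
    cells_per_gds: float  # cells per g dry stool
    biomass_g_per_gds: float  # g_DW per g dry stool
    dry_stool_activity: float  # umol per g dry stool per h
    colon_dry_mass_g: float
    total_activity: float  # umol/h


def colon_dry_mass(phys: StoolPhysiology) -> float:
    """Dry mass of the colonic content: wet volume x density x (1 - water)."""
    return phys.wet_volume_ml * phys.density_g_per_ml * (1.0 - phys.water_fraction)


def taxon_cells_per_gds(profile: TaxonProfile, phys: StoolPhysiology) -> float:
    """Taxon cells per g dry stool: abundance x total bacterial count."""
    return profile.abundance * phys.cells_per_g_dry_stool


def biomass_per_gds(cells_per_gds: float, phys: StoolPhysiology) -> float:
    """Taxon dry biomass per g dry stool via the average per-cell mass."""
    return cells_per_gds * phys.per_cell_dw


def activity_chain(profile: TaxonProfile, phys: StoolPhysiology) -> ColonActivityResult:
    """The full chain from abundance to total colonic activity (umol/h)."""
    cells = taxon_cells_per_gds(profile, phys)
    biomass = biomass_per_gds(cells, phys)
    dry_stool_activity = profile.specific_activity * biomass
    mass = colon_dry_mass(phys)
    return ColonActivityResult(
        species=profile.species,
        cells_per_gds=cells,
        biomass_g_per_gds=biomass,
        dry_stool_activity=dry_stool_activity,
        colon_dry_mass_g=mass,
        total_activity=dry_stool_activity * mass,
    )


def bolus_amount(scen: BolusScenario) -> float:
    """Nitrite amount in the bolus, umol: conc (umol/L) x volume (L)."""
    return scen.conc_uM * scen.volume_ml / 1000.0


def detox_time(amount_umol: float, total_activity: float) -> float:
    """Minutes to clear the bolus at constant (zero-order) total activity."""
    if amount_umol < 0:
        raise ValueError("amount must be >= 0")
    if total_activity < 0:
        raise ValueError("total_activity must be >= 0")
    if total_activity == 0:
        return 0.0 if amount_umol == 0 else math.inf
    return amount_umol / total_activity * 60.0


def back_estimate_abundance(
    community_specific_activity: float, reference: TaxonProfile
) -> float:
    """Implied abundance (%) of the reference taxon if it carried all activity."""
    if reference.specific_activity <= 0:
        raise ValueError("reference specific activity must be > 0")
    return community_specific_activity / reference.specific_activity * 100.0


def mixture_activity(profiles) -> float:
    """Abundance-weighted mean specific activity of a mixed community.

    Weights renormalize over the included taxa (a partial community still
    makes a valid mixture).
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one taxon profile")
    total = sum(p.abundance for p in profiles)
    if total == 0:
        raise ValueError("all abundances are zero")
    return sum(p.abundance * p.specific_activity for p in profiles) / total
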