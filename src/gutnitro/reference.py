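"""Bundled reference measurements and physiological constants.

These are published reference values for the human gut microbiota used as
*inputs* by the pipeline: per-species counting-chamber/dry-weight
calibrations, measured nitrite specific activities with colonic relative
abundances, and the stool physiology constants behind the organ-scale
extrapolation. Activities quoted "< x" in the source (below the reporting
threshold) carry a censoring flag and an activity of 0.
"""

from __future__ import annotations

import pandas as pd

from .biomass import SpeciesBiomass, species_biomass_row
from .colon import StoolPhysiology, TaxonProfile

__all__ = [
    "gut_species_biomass",
    "colon_taxon_profiles",
    "DEFAULT_STOOL_PHYSIOLOGY",
    "ECOLI_ACTIVITY_MEASURED",
    "ECOLI_ACTIVITY_MEASURED_SD",
    "ECOLI_ACTIVITY_EXTRAPOLATION",
    "ECOLI_ABUNDANCE",
    "FECES_ACTIVITY",
    "FECES_ACTIVITY_SD",
    "GUT_MIX_ACTIVITY",
    "COMMUNITY_PER_CELL_DW",
]

# Measured E. coli K-12 nitrite specific activity (umol g_DW^-1 h^-1):
# replicate mean +/- sd, and the slightly different rounding used in the
# organ-scale extrapolation table.
ECOLI_ACTIVITY_MEASURED = 10770.0
ECOLI_ACTIVITY_MEASURED_SD = 2183.0
ECOLI_ACTIVITY_EXTRAPOLATION = 10966.0
ECOLI_ABUNDANCE = 0.008  # fraction of colonic cells

# Fecal community nitrite specific activity over five subjects.
FECES_ACTIVITY = 74.4
FECES_ACTIVITY_SD = 24.5
# Synthetic mixed-community (resting cells) peak activity.
GUT_MIX_ACTIVITY = 70.0

# Community-average dry mass of a single gut bacterium (g).
COMMUNITY_PER_CELL_DW = 2.52e-13

DEFAULT_STOOL_PHYSIOLOGY = StoolPhysiology()

# species, cells L^-1 OD^-1, dry weight g L^-1 OD^-1 (None: no DW determined)
_BIOMASS_ROWS = [
    ("Agathobacter rectalis", 1.85e12, 0.41),
    ("Akkermansia muciniphila", 2.55e12, 0.41),
    ("Anaerostipes hadrus", 6.95e11, None),
    ("Bacteroides cellulosilyticus", 1.14e12, 0.31),
    ("Bacteroides xylanisolvens", 2.23e12, 0.36),
    ("Bifidobacterium adolescentis", 1.41e12, 0.42),
    ("Blautia faecis", 1.69e12, 0.45),
    ("Escherichia coli", 8.00e11, 0.22),
    ("Faecalibacterium prausnitzii", 1.17e12, 0.41),
    ("Mediterraneibacter gnavus", 9.78e11, 0.25),
    ("Parabacteroides johnsonii", 1.52e12, 0.40),
    ("Phocaeicola dorei", 1.61e12, 0.23),
    ("Phocaeicola vulgatus", 1.03e12, 0.36),
    ("Segatella copri", 1.44e12, 0.40),
]

# printed per-cell dry masses (g) for cross-checking recomputation
PUBLISHED_PER_CELL_DW = {
    "Agathobacter rectalis": 2.19e-13,
    "Akkermansia muciniphila": 1.62e-13,
    "Bacteroides cellulosilyticus": 2.72e-13,
    "Bacteroides xylanisolvens": 1.61e-13,
    "Bifidobacterium adolescentis": 2.98e-13,
    "Blautia faecis": 2.63e-13,
    "Escherichia coli": 2.80e-13,
    "Faecalibacterium prausnitzii": 3.51e-13,
    "Mediterraneibacter gnavus": 2.56e-13,
    "Parabacteroides johnsonii": 2.63e-13,
    "Phocaeicola dorei": 1.43e-13,
    "Phocaeicola vulgatus": 3.50e-13,
    "Segatella copri": 2.78e-13,
}


def gut_species_biomass(include_missing_dw: bool = False) -> pd.DataFrame:
    """Per-species counting/dry-weight calibration table.

    Columns: ``species, cells_per_l_per_od, dw_g_per_l_per_od``. Species with
    no dry-weight determination are dropped unless ``include_missing_dw``.
    """
    df = pd.DataFrame(
        _BIOMASS_ROWS, columns=["species", "cells_per_l_per_od", "dw_g_per_l_per_od"]
    )
    if not include_missing_dw:
        df = df.dropna(subset=["dw_g_per_l_per_od"]).reset_index(drop=True)
    return df


def gut_species_biomass_rows() -> list[SpeciesBiomass]:
    """The same table as :class:`SpeciesBiomass` records (DW-complete only)."""
    df = gut_species_biomass()
    return [
        species_biomass_row(r.species, r.cells_per_l_per_od, r.dw_g_per_l_per_od)
        for r in df.itertuples()
    ]


# species, relative abundance (% of colonic cells), measured nitrite specific
# activity (umol g_DW^-1 h^-1; 0 + censored flag for "< threshold" entries),
# sd, reporting threshold for censored entries
_COLON_TAXA = [
    ("Agathobacter rectalis", 6.2, 0.0, 0.0, 1.0),
    ("Akkermansia muciniphila", 0.7, 0.0, 0.0, 1.0),
    ("Bacteroides cellulosilyticus", 3.4, 26.9, 12.2, None),
    ("Bacteroides xylanisolvens", 4.9, 110.4, 27.5, None),
    ("Bifidobacterium longum", 0.7, 2.2, 0.2, None),
    ("Escherichia coli K-12", 0.8, ECOLI_ACTIVITY_MEASURED, ECOLI_ACTIVITY_MEASURED_SD, None),
    ("Faecalibacterium prausnitzii", 3.5, 0.0, 0.0, 2.0),
    ("Hominimerdicola aceti", 2.5, 0.0, 0.0, 1.0),
    ("Phocaeicola dorei", 17.4, 10.6, 6.2, None),
    ("Phocaeicola vulgatus", 15.0, 55.3, 32.2, None),
    ("Roseburia intestinalis", 1.1, 29.3, 10.9, None),
]


def colon_taxon_profiles(as_frame: bool = False):
    """Measured colonic taxa: abundance (fraction) and specific activity.

    Returns :class:`TaxonProfile` records by default (censored "< x" entries
    enter with activity 0), or a DataFrame with the censoring detail.
    """
    if as_frame:
        return pd.DataFrame(
            _COLON_TAXA,
            columns=[
                "species",
                "abundance_pct",
                "activity",
                "activity_sd",
                "censored_below",
            ],
        )
    return [
        TaxonProfile(species=s, abundance=a / 100.0, specific_activity=act)
        for s, a, act, _sd, _cb in _COLON_TAXA
    ]
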