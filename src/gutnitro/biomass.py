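"""Cell counting and dry-weight calibration: cells/OD, g_DW/OD, per-cell mass.

A Thoma-type counting chamber turns counts per main square into cells per mL
through the known square volume (area x depth). Dry weights measured at
several OD levels are regressed against the corresponding cell numbers; the
origin-constrained slope is the dry mass of a single cell (zero cells must
mean zero mass). Averaging the per-cell mass over species from the major gut
phyla gives the community-average cell mass used by the colon extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "CountingChamberSpec",
    "SpeciesBiomass",
    "CommunityAverage",
    "CellMassCalibration",
    "counts_to_concentration",
    "per_cell_dw_from_regression",
    "species_biomass_row",
    "community_average",
    "average_drying_measurements",
]


@dataclass(frozen=True)
class CountingChamberSpec:
    """Counting-chamber geometry; defaults match a standard Thoma chamber."""

    depth_mm: float = 0.02
    square_area_mm2: float = 0.0025
    squares_counted: int = 4
    dilution: float = 1.0

    def __post_init__(self) -> None:
        if min(self.depth_mm, self.square_area_mm2, self.dilution) <= 0:
            raise ValueError("chamber dimensions and dilution must be > 0")
        if self.squares_counted < 1:
            raise ValueError("squares_counted must be >= 1")

    @property
    def square_volume_ml(self) -> float:
        # mm^3 -> mL: 1 mm^3 = 1e-3 mL
        return self.square_area_mm2 * self.depth_mm * 1e-3


def counts_to_concentration(
    mean_count_per_square: float, spec: CountingChamberSpec = CountingChamberSpec()
) -> float:
    """Cells per mL from the mean count per main square.

    cells/mL = count x dilution / square volume; the default square volume is
    0.0025 mm^2 x 0.02 mm = 5e-8 mL, so 20 cells/square means 4e8 cells/mL.
    """
    if mean_count_per_square < 0:
        raise ValueError("counts must be >= 0")
    return mean_count_per_square * spec.dilution / spec.square_volume_ml


class CellMassCalibration(BaseEstimator):
    """Per-cell dry mass from paired (cell number, dry weight) observations.

    Fits an origin-constrained least-squares line DW = m x N; the slope ``m``
    is the dry mass of one cell (``per_cell_dw_``, in g).
    """

    def fit(self, cell_numbers, dry_weights) -> "CellMassCalibration":
        n = np.asarray(cell_numbers, dtype=float)
        dw = np.asarray(dry_weights, dtype=float)
        if n.shape != dw.shape or n.ndim != 1:
            raise ValueError("cell_numbers and dry_weights must be 1-D and equal length")
        if n.size < 2:
            raise ValueError("need at least 2 paired observations")
        if np.ptp(n) == 0:
            raise ValueError("all cell numbers are equal; vary the harvest OD")
        self.per_cell_dw_ = float(n @ dw) / float(n @ n)
        return self

    def predict(self, cell_numbers):
        return self.per_cell_dw_ * np.asarray(cell_numbers, dtype=float)


def per_cell_dw_from_regression(cell_numbers, dry_weights) -> float:
    """Origin-constrained slope of dry weight vs cell number (g per cell)."""
    return CellMassCalibration().fit(cell_numbers, dry_weights).per_cell_dw_


@dataclass(frozen=True)
class SpeciesBiomass:
    """One species' biomass calibration: cells/OD, dry weight/OD, per-cell mass."""

    species: str
    cells_per_l_per_od: float
    dw_per_l_per_od: float
    per_cell_dw: float

    def __post_init__(self) -> None:
        if min(self.cells_per_l_per_od, self.dw_per_l_per_od, self.per_cell_dw) <= 0:
            raise ValueError("biomass quantities must be > 0")


def species_biomass_row(
    species: str, cells_per_l_per_od: float, dw_per_l_per_od: float
) -> SpeciesBiomass:
    """Per-cell dry mass as the quotient of the per-OD columns."""
    if cells_per_l_per_od <= 0:
        raise ValueError("cells_per_l_per_od must be > 0")
    return SpeciesBiomass(
        species=species,
        cells_per_l_per_od=cells_per_l_per_od,
        dw_per_l_per_od=dw_per_l_per_od,
        per_cell_dw=dw_per_l_per_od / cells_per_l_per_od,
    )


@dataclass(frozen=True)
class CommunityAverage:
    mean_per_cell_dw: float
    sd: float
    n_species: int


def community_average(rows) -> CommunityAverage:
    """Arithmetic mean +/- sample sd of per-cell dry mass over species.

    Species lacking a dry-weight determination are expected to be absent from
    ``rows`` (they cannot form a :class:`SpeciesBiomass`).
    """
    values = np.array([r.per_cell_dw for r in rows], dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 species with per-cell dry mass")
    return CommunityAverage(
        mean_per_cell_dw=float(values.mean()),
        sd=float(values.std(ddof=1)),
        n_species=int(values.size),
    )


def average_drying_measurements(
    dw_24h: float, dw_48h: float, rel_tol: float = 0.05
) -> tuple[float, bool]:
    """Mean of the 24 h and 48 h drying measurements; flags >5% discrepancy."""
    mean = (dw_24h + dw_48h) / 2.0
    flagged = mean > 0 and abs(dw_24h - dw_48h) / mean > rel_tol
    return mean, bool(flagged)


def biomass_table(rows) -> pd.DataFrame:
    """Tabulate SpeciesBiomass rows plus the community average/sd lines."""
    df = pd.DataFrame(
        {
            "species": [r.species for r in rows],
            "cells_per_l_per_od": [r.cells_per_l_per_od for r in rows],
            "dw_g_per_l_per_od": [r.dw_per_l_per_od for r in rows],
            "per_cell_dw_g": [r.per_cell_dw for r in rows],
        }
    )
    avg = community_average(rows)
    summary = pd.DataFrame(
        {
            "species": ["Average", "StDV"],
            "cells_per_l_per_od": [df["cells_per_l_per_od"].mean(), df["cells_per_l_per_od"].std(ddof=1)],
            "dw_g_per_l_per_od": [df["dw_g_per_l_per_od"].mean(), df["dw_g_per_l_per_od"].std(ddof=1)],
            "per_cell_dw_g": [avg.mean_per_cell_dw, avg.sd],
        }
    )
    return pd.concat([df, summary], ignore_index=True)
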