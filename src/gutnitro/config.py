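"""YAML round trip for the shared physiological/correction configuration.

Keys carry explicit units so a config file documents itself, e.g.::

    stool:
      cells_per_g_dry_stool: 3.23e11
      wet_volume_ml: 400
      density_g_per_ml: 1.04
      water_fraction: 0.75
      per_cell_dw_g: 2.52e-13
    abiotic:
      cysteine_mM: 1.5
      cysteine_loss_per_mM: 33.333
      background_decay_per_h: 0.00439
      ph_decay_table:       # pH -> h^-1, below pH 5.8
        4.0: 0.05
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .colon import StoolPhysiology
from .params import AbioticModelParams

__all__ = ["load_config", "dump_config", "physiology_from_dict", "abiotic_from_dict"]


def physiology_from_dict(d: dict) -> StoolPhysiology:
    return StoolPhysiology(
        cells_per_g_dry_stool=float(d.get("cells_per_g_dry_stool", 3.23e11)),
        wet_volume_ml=float(d.get("wet_volume_ml", 400.0)),
        density_g_per_ml=float(d.get("density_g_per_ml", 1.04)),
        water_fraction=float(d.get("water_fraction", 0.75)),
        per_cell_dw=float(d.get("per_cell_dw_g", 2.52e-13)),
    )


def abiotic_from_dict(d: dict) -> AbioticModelParams:
    defaults = AbioticModelParams()
    return AbioticModelParams(
        cysteine_mM=float(d.get("cysteine_mM", defaults.cysteine_mM)),
        cysteine_loss_per_mM=float(
            d.get("cysteine_loss_per_mM", defaults.cysteine_loss_per_mM)
        ),
        ph_decay_table={
            float(k): float(v) for k, v in (d.get("ph_decay_table") or {}).items()
        },
        background_decay_per_h=float(
            d.get("background_decay_per_h", defaults.background_decay_per_h)
        ),
    )


def load_config(path: str | Path) -> tuple[StoolPhysiology, AbioticModelParams]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return (
        physiology_from_dict(raw.get("stool") or {}),
        abiotic_from_dict(raw.get("abiotic") or {}),
    )


def dump_config(
    path: str | Path, phys: StoolPhysiology, abiotic: AbioticModelParams
) -> None:
    payload = {
        "stool": {
            "cells_per_g_dry_stool": phys.cells_per_g_dry_stool,
            "wet_volume_ml": phys.wet_volume_ml,
            "density_g_per_ml": phys.density_g_per_ml,
            "water_fraction": phys.water_fraction,
            "per_cell_dw_g": phys.per_cell_dw,
        },
        "abiotic": {
            "cysteine_mM": abiotic.cysteine_mM,
            "cysteine_loss_per_mM": abiotic.cysteine_loss_per_mM,
            "background_decay_per_h": abiotic.background_decay_per_h,
            "ph_decay_table": dict(abiotic.ph_decay_table),
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
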