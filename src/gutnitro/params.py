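"""Parameter types shared by the simulator and the correction/kinetics modules.

Units are fixed throughout the package: time in hours, concentrations in
micromolar (uM == umol/L), optical density at 600 nm (dimensionless), biomass
as g dry weight per litre, specific activity in umol per g dry weight per
hour. Rescaling to other units is supported everywhere (the maths is
unit-agnostic) but the defaults are stated in these units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GrowthModelParams",
    "ConsumptionModelParams",
    "AbioticModelParams",
    "NoiseSpec",
    "BACKGROUND_PH_DECAY_PER_H",
    "DEFAULT_BIOMASS_PER_OD",
    "DEFAULT_CYSTEINE_LOSS_PER_MM",
    "DEFAULT_CYSTEINE_LOSS_24H_PER_MM",
]

#: First-order abiotic decay at pH >= 5.8: ~10% loss of nitrite over 24 h in
#: buffered complex medium, expressed as a rate constant (-ln 0.9 / 24 h).
BACKGROUND_PH_DECAY_PER_H: float = -math.log(0.9) / 24.0

#: Community-average dry weight per litre per OD600 unit (g L^-1 OD^-1).
DEFAULT_BIOMASS_PER_OD: float = 0.36

#: Instantaneous nitrite scavenging by L-cysteine (uM lost per mM cysteine),
#: anchored so that 150 uM nominal with 1.5 mM cysteine yields 100 uM.
DEFAULT_CYSTEINE_LOSS_PER_MM: float = 50.0 / 1.5

#: Slow (24 h horizon) cysteine-dependent loss, anchored so that 150 uM with
#: 4 mM cysteine ends near 80 uM after 24 h: (150 - 80)/4 uM per mM.
DEFAULT_CYSTEINE_LOSS_24H_PER_MM: float = 70.0 / 4.0


def _check_finite(name: str, value: float) -> None:
    if not np.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class GrowthModelParams:
    """Lag + logistic growth curve parameters.

    ``mu_max`` is the maximum *specific* growth rate (h^-1) actually realised
    by the curve, so the doubling time is ``ln 2 / mu_max``.
    """

    od_initial: float = 0.05
    od_max: float = 0.6
    mu_max: float = math.log(2) / 1.1
    lag: float = 5.0

    def __post_init__(self) -> None:
        for name in ("od_initial", "od_max", "mu_max", "lag"):
            _check_finite(name, getattr(self, name))
        if not self.od_initial > 0:
            raise ValueError("od_initial must be > 0")
        if self.od_max < self.od_initial:
            raise ValueError("od_max must be >= od_initial")
        if self.mu_max < 0 or self.lag < 0:
            raise ValueError("mu_max and lag must be >= 0")

    @property
    def doubling_time(self) -> float:
        """Doubling time ln2/mu_max in hours (inf for zero growth)."""
        return math.inf if self.mu_max == 0 else math.log(2) / self.mu_max


@dataclass(frozen=True)
class ConsumptionModelParams:
    """Enzymatic substrate-depletion parameters.

    ``specific_activity`` (umol g_DW^-1 h^-1) is the saturated turnover per g
    dry weight; ``km`` (uM) the half-saturation of the depletion law;
    ``biomass_per_od`` converts OD600 to g dry weight per litre.
    """

    specific_activity: float = 100.0
    km: float = 20.0
    biomass_per_od: float = DEFAULT_BIOMASS_PER_OD

    def __post_init__(self) -> None:
        for name in ("specific_activity", "km", "biomass_per_od"):
            _check_finite(name, getattr(self, name))
        if self.specific_activity < 0 or self.km < 0:
            raise ValueError("specific_activity and km must be >= 0")
        if not self.biomass_per_od > 0:
            raise ValueError("biomass_per_od must be > 0")


@dataclass(frozen=True)
class AbioticModelParams:
    """Abiotic nitrite losses: cysteine scavenging and pH-dependent decay.

    Cysteine removes nitrite essentially instantaneously at t = 0
    (``cysteine_loss_per_mM`` uM per mM cysteine). pH-dependent decay is
    first-order: below pH 5.8 rates come from ``ph_decay_table`` (pH ->
    h^-1, linearly interpolated); at and above pH 5.8 a small background
    rate applies (~10% loss over 24 h by default).
    """

    cysteine_mM: float = 1.5
    cysteine_loss_per_mM: float = DEFAULT_CYSTEINE_LOSS_PER_MM
    ph_decay_table: dict[float, float] = field(default_factory=dict)
    background_decay_per_h: float = BACKGROUND_PH_DECAY_PER_H

    def __post_init__(self) -> None:
        for name in ("cysteine_mM", "cysteine_loss_per_mM", "background_decay_per_h"):
            _check_finite(name, getattr(self, name))
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for ph, rate in self.ph_decay_table.items():
            if rate < 0:
                raise ValueError(f"decay rate at pH {ph} must be >= 0")

    @classmethod
    def zero(cls) -> "AbioticModelParams":
        """An all-zero correction (no cysteine, no decay); handy for controls."""
        return cls(cysteine_mM=0.0, cysteine_loss_per_mM=0.0, background_decay_per_h=0.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model: same seed, same output, byte for byte."""

    od_cv: float = 0.0
    conc_sd: float = 0.0
    absorbance_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.od_cv < 0 or self.conc_sd < 0 or self.absorbance_sd < 0:
            raise ValueError("noise magnitudes must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    @classmethod
    def off(cls) -> "NoiseSpec":
        return cls()
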