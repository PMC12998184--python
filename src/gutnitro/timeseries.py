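"""The incubation-assay time series container and its CSV round trip."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["AssayTimeSeries"]

_ANALYTES = ("nitrite", "nitrate")
_MODES = ("growing", "resting")


@dataclass
class AssayTimeSeries:
    """One incubation experiment: OD600, analyte concentration and pH over time.

    ``conc`` holds the measured concentration in uM; ``censored`` marks values
    below the detection limit. Censored entries keep their raw estimate but
    must never be treated as quantitative — downstream fits exclude them.
    """

    time: np.ndarray  # h
    od600: np.ndarray
    conc: np.ndarray  # uM
    ph: np.ndarray
    analyte: str = "nitrite"
    mode: str = "growing"
    species: str | None = None
    censored: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        ph = self.ph
        if np.isscalar(ph):
            ph = np.full_like(self.time, float(ph))
        self.ph = np.asarray(ph, dtype=float)
        if self.censored is None:
            self.censored = np.zeros(self.time.shape, dtype=bool)
        self.censored = np.asarray(self.censored, dtype=bool)
        n = self.time.size
        if n == 0:
            raise ValueError("time series must contain at least one point")
        for name in ("od600", "conc", "ph", "censored"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length does not match time")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.analyte not in _ANALYTES:
            raise ValueError(f"analyte must be one of {_ANALYTES}")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")

    def __len__(self) -> int:
        return self.time.size

    def with_lod(self, lod: float = 10.0) -> "AssayTimeSeries":
        """Return a copy with values below ``lod`` (uM) marked censored."""
        mask = self.censored | (self.conc < lod)
        return replace(self, censored=mask)

    @property
    def n_uncensored(self) -> int:
        return int((~self.censored).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.time,
                "od600": self.od600,
                "conc_uM": self.conc,
                "ph": self.ph,
                "censored": self.censored.astype(int),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        analyte: str = "nitrite",
        mode: str = "growing",
        species: str | None = None,
    ) -> "AssayTimeSeries":
        censored = df["censored"].to_numpy(dtype=bool) if "censored" in df else None
        return cls(
            time=df["time_h"].to_numpy(dtype=float),
            od600=df["od600"].to_numpy(dtype=float),
            conc=df["conc_uM"].to_numpy(dtype=float),
            ph=df["ph"].to_numpy(dtype=float) if "ph" in df else np.full(len(df), 7.0),
            analyte=analyte,
            mode=mode,
            species=species,
            censored=censored,
        )

    @classmethod
    def from_csv(cls, path: str | Path, **meta) -> "AssayTimeSeries":
        return cls.from_frame(pd.read_csv(path), **meta)
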