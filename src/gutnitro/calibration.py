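"""Colorimetric (Griess/Lunge-type) assay calibration and abiotic corrections.

The azo-dye assay is linear in nitrite over the working range (0-100 uM), so
calibration is an ordinary least-squares line from standards, inverted to map
absorbance at 540 nm back to concentration. Values below the detection limit
(10 uM by default) propagate as an explicit censored state, never as zero.

Abiotic losses have two channels: an effectively instantaneous scavenging of
nitrite by the reducing agent L-cysteine at the start of the incubation, and a
slow first-order decay that is strongly pH dependent (protonation to
HNO2/NO+ below pH 5.8; only a ~10%-per-24 h background above).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.integrate import cumulative_trapezoid
from sklearn.base import BaseEstimator

from .params import (
    AbioticModelParams,
    DEFAULT_CYSTEINE_LOSS_24H_PER_MM,
)
from .timeseries import AssayTimeSeries

__all__ = [
    "AbioticCorrection",
    "CalibrationCurve",
    "CensoredConcentration",
    "GriessCalibration",
    "fit_calibration",
    "absorbance_to_concentration",
    "effective_initial_nitrite",
    "cysteine_loss_24h",
    "abiotic_decay_rate",
    "subtract_abiotic",
]

#: Abiotic corrections share their semantics with the simulator's loss model.
AbioticCorrection = AbioticModelParams

_PH_PLATEAU = 5.8  # above this pH only the background decay applies
_PH_RANGE = (3.0, 9.0)


@dataclass(frozen=True)
class CensoredConcentration:
    """A concentration that may sit below the assay's detection limit.

    ``value`` always carries the raw linear estimate (possibly negative for
    blanks); ``censored`` says whether it is quantitative. Censored values
    are reported as ``"< lod uM"`` and must be excluded from fits.
    """

    value: float
    censored: bool
    lod: float

    @property
    def reported(self) -> float | None:
        return None if self.censored else self.value

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"<{self.lod:g} uM" if self.censored else f"{self.value:.3g} uM"


class GriessCalibration(BaseEstimator):
    """Linear absorbance-vs-concentration calibration with LOD censoring.

    Parameters
    ----------
    lod : float, default 10.0
        Detection limit in uM. Estimates below it (or negative) come back
        censored.

    Attributes
    ----------
    slope_ : float
        Absorbance per uM.
    intercept_ : float
        Blank absorbance.
    r2_ : float
        Coefficient of determination of the standards fit.
    """

    def __init__(self, lod: float = 10.0):
        self.lod = lod

    def fit(self, conc, absorbance) -> "GriessCalibration":
        conc = np.asarray(conc, dtype=float)
        absorbance = np.asarray(absorbance, dtype=float)
        if conc.shape != absorbance.shape or conc.ndim != 1:
            raise ValueError("conc and absorbance must be 1-D and equally long")
        if np.unique(conc).size < 3:
            raise ValueError("need at least 3 distinct standard levels")
        if np.ptp(conc) == 0:
            raise ValueError("standards have zero variance in concentration")
        res = stats.linregress(conc, absorbance)
        if not res.slope > 0:
            raise ValueError(
                "degenerate calibration: non-positive slope "
                f"({res.slope:.3g} abs/uM); check the standards"
            )
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r2_ = float(res.rvalue**2)
        return self

    def to_concentration(self, absorbance):
        """Invert the line; returns (values uM, censored mask)."""
        a = np.asarray(absorbance, dtype=float)
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance must be finite")
        values = (a - self.intercept_) / self.slope_
        censored = (values < self.lod) | (values < 0)
        return values, censored

    def curve(self) -> "CalibrationCurve":
        return CalibrationCurve(
            slope=self.slope_, intercept=self.intercept_, r2=self.r2_, lod=self.lod
        )


@dataclass(frozen=True)
class CalibrationCurve:
    """Frozen result of a standards fit (slope in abs/uM)."""

    slope: float
    intercept: float
    r2: float
    lod: float = 10.0

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("slope must be > 0")
        if not 0 <= self.r2 <= 1 + 1e-12:
            raise ValueError("r2 must lie in [0, 1]")
        if self.lod < 0:
            raise ValueError("lod must be >= 0")


def fit_calibration(standards) -> CalibrationCurve:
    """OLS fit of a standards table with columns ``conc_uM, absorbance``."""
    est = GriessCalibration().fit(
        np.asarray(standards["conc_uM"]), np.asarray(standards["absorbance"])
    )
    return est.curve()


def absorbance_to_concentration(curve: CalibrationCurve, a: float) -> CensoredConcentration:
    """Map one absorbance reading to a (possibly censored) concentration."""
    if not np.isfinite(a):
        raise ValueError("absorbance must be finite")
    value = (a - curve.intercept) / curve.slope
    return CensoredConcentration(
        value=float(value), censored=bool(value < curve.lod or value < 0), lod=curve.lod
    )


def effective_initial_nitrite(
    nominal: float, cysteine_mM: float, corr: AbioticCorrection
) -> float:
    """Initial nitrite after the seconds-scale cysteine scavenging, floored at 0."""
    if nominal < 0:
        raise ValueError("nominal concentration must be >= 0")
    return max(nominal - corr.cysteine_loss_per_mM * cysteine_mM, 0.0)


def cysteine_loss_24h(
    nominal: float,
    cysteine_mM: float,
    loss_per_mM_24h: float = DEFAULT_CYSTEINE_LOSS_24H_PER_MM,
) -> float:
    """Long-horizon (24 h) nitrite remaining given slow cysteine consumption.

    This is the empirical near-linear 24 h trend against cysteine
    concentration, distinct from the instantaneous scavenging channel used
    for initial-concentration correction.
    """
    return max(nominal - loss_per_mM_24h * cysteine_mM, 0.0)


def abiotic_decay_rate(ph: float, corr: AbioticCorrection) -> float:
    """First-order abiotic nitrite decay rate (h^-1) at a given pH.

    At pH >= 5.8 the background rate applies (default ~10% loss per 24 h).
    Below 5.8 rates are interpolated linearly from the user-supplied table;
    table entries are honoured verbatim at their own pH.
    """
    if not _PH_RANGE[0] <= ph <= _PH_RANGE[1]:
        raise ValueError(f"pH {ph} outside supported range {_PH_RANGE}")
    table = {p: r for p, r in corr.ph_decay_table.items() if p < _PH_PLATEAU}
    if ph in corr.ph_decay_table:
        return float(corr.ph_decay_table[ph])
    if ph >= _PH_PLATEAU:
        return float(corr.background_decay_per_h)
    if not table:
        raise ValueError(
            f"pH {ph} is below {_PH_PLATEAU} but no acidic decay table was provided"
        )
    knots = sorted(table.items()) + [(_PH_PLATEAU, corr.background_decay_per_h)]
    phs = np.array([k[0] for k in knots])
    rates = np.array([k[1] for k in knots])
    if ph < phs[0]:
        raise ValueError(f"pH {ph} below the tabulated range (min {phs[0]})")
    return float(np.interp(ph, phs, rates))


def subtract_abiotic(series: AssayTimeSeries, corr: AbioticCorrection) -> AssayTimeSeries:
    """Remove the first-order abiotic component from a concentration course.

    Multiplies each measurement by exp(int_0^t k(pH) dtau) so that a purely
    abiotic series becomes constant and downstream rates reflect enzymatic
    activity only. A no-op when all rates are zero.
    """
    if np.any(~np.isfinite(series.ph)):
        raise ValueError("pH must be recorded at every timepoint")
    rates = np.array([abiotic_decay_rate(p, corr) for p in series.ph])
    integral = cumulative_trapezoid(rates, series.time, initial=0.0)
    corrected = series.conc * np.exp(integral)
    return replace(series, conc=corrected)
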