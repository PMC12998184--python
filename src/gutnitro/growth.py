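"""Growth-parameter extraction and nitrite growth-inhibition phenotyping.

From a background-subtracted OD600 curve the estimator extracts the maximum
specific growth rate (steepest log-linear window), the lag (tangent-intercept
on log OD), the maximum smoothed OD, and a no-growth flag. A dose series of
such fits over nitrite concentrations forms an inhibition profile, which is
classified into one of four phenotypes:

* ``insensitive`` - no parameter shifts beyond the relative-change threshold;
* ``lag_extension`` - lag and/or doubling time increase, capacity unchanged;
* ``capacity_loss`` - maximum OD declines;
* ``complete_inhibition_above_threshold`` - no growth at and above some
  concentration.

Precedence when signatures mix: complete inhibition > capacity loss > lag
extension > insensitive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "GrowthParameters",
    "InhibitionProfile",
    "PhenotypeClass",
    "GrowthCurveFit",
    "fit_growth_parameters",
    "build_profile",
    "classify_phenotype",
]


@dataclass(frozen=True)
class GrowthParameters:
    lag: float  # h
    doubling_time: float  # h
    od_max: float
    r2: float  # fit quality of the steepest log-linear window
    no_growth: bool = False


@dataclass(frozen=True)
class PhenotypeClass:
    kind: str  # insensitive | lag_extension | capacity_loss | complete_inhibition_above_threshold
    threshold_conc: float | None = None  # lowest no-growth concentration


class InhibitionProfile(dict):
    """Mapping nitrite concentration (uM) -> GrowthParameters; must contain 0."""

    def __init__(self, data):
        super().__init__(data)
        if 0 not in self and 0.0 not in self:
            raise ValueError("profile must contain a 0 uM reference")

    @property
    def reference(self) -> GrowthParameters:
        return self[0] if 0 in self else self[0.0]

    @property
    def no_growth_concs(self) -> list[float]:
        return sorted(c for c, p in self.items() if p.no_growth)


class GrowthCurveFit(BaseEstimator):
    """Growth parameters from one OD600 curve.

    Parameters
    ----------
    window : int, default 5
        Number of points in the sliding log-linear window used to find the
        maximum specific growth rate.
    smooth : int, default 3
        Centered moving-average span applied to the OD before analysis.
    min_rise : float, default 0.05
        Minimum OD rise above baseline to call growth at all.

    Attributes (after ``fit``)
    --------------------------
    mu_max_, doubling_time_, lag_, od_max_, r2_, no_growth_
    """

    def __init__(self, window: int = 5, smooth: int = 3, min_rise: float = 0.05):
        self.window = window
        self.smooth = smooth
        self.min_rise = min_rise

    def fit(self, time, od) -> "GrowthCurveFit":
        t = np.asarray(time, dtype=float)
        od = np.asarray(od, dtype=float)
        if t.size < 8:
            raise ValueError("need at least 8 timepoints")
        if np.any(od <= 0):
            raise ValueError("OD must be positive after background subtraction")
        od_s = (
            pd.Series(od).rolling(self.smooth, center=True, min_periods=1).mean().to_numpy()
        )
        baseline = float(np.median(od_s[:3]))
        self.od_max_ = float(od_s.max())
        if self.od_max_ < baseline + self.min_rise:
            self.no_growth_ = True
            self.mu_max_ = 0.0
            self.doubling_time_ = math.inf
            self.lag_ = math.nan
            self.r2_ = math.nan
            return self

        self.no_growth_ = False
        y = np.log(od_s)
        w = self.window
        best = (-math.inf, 0.0, 0.0, 0.0)  # slope, intercept, r2, t_mid
        for i in range(t.size - w + 1):
            ts, ys = t[i : i + w], y[i : i + w]
            slope, intercept = np.polyfit(ts, ys, 1)
            if slope > best[0]:
                pred = slope * ts + intercept
                ss_res = float(((ys - pred) ** 2).sum())
                ss_tot = float(((ys - ys.mean()) ** 2).sum())
                r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
                best = (slope, intercept, r2, float(ts.mean()))
        slope, intercept, r2, _ = best
        self.mu_max_ = max(float(slope), 0.0)
        self.r2_ = float(r2)
        if self.mu_max_ == 0.0:
            self.doubling_time_ = math.inf
            self.lag_ = math.nan
        else:
            self.doubling_time_ = math.log(2) / self.mu_max_
            # tangent-intercept lag: where the steepest log-linear tangent
            # crosses the initial log OD
            self.lag_ = max((math.log(baseline) - intercept) / self.mu_max_, 0.0)
        return self

    def params(self) -> GrowthParameters:
        return GrowthParameters(
            lag=self.lag_,
            doubling_time=self.doubling_time_,
            od_max=self.od_max_,
            r2=self.r2_,
            no_growth=self.no_growth_,
        )


def fit_growth_parameters(time, od, **kwargs) -> GrowthParameters:
    """Lag, doubling time, maximum OD and a no-growth flag from one curve."""
    return GrowthCurveFit(**kwargs).fit(time, od).params()


def build_profile(curves: dict, **kwargs) -> InhibitionProfile:
    """Fit every concentration's curve; ``curves`` maps conc -> (time, od)."""
    if 0 not in curves and 0.0 not in curves:
        raise ValueError("a 0 uM reference curve is required")
    return InhibitionProfile(
        {conc: fit_growth_parameters(t, od, **kwargs) for conc, (t, od) in curves.items()}
    )


def _rel_increase(value: float, ref: float, floor: float = 0.5) -> float:
    # guard against near-zero reference lags blowing up the ratio
    if not np.isfinite(value) or not np.isfinite(ref):
        return 0.0
    return (value - ref) / max(ref, floor)


def classify_phenotype(
    profile: InhibitionProfile, rel_change_threshold: float = 0.25
) -> PhenotypeClass:
    """Assign one inhibition phenotype to a dose-response profile."""
    if len(profile) < 3:
        raise ValueError("need at least 3 concentrations to classify")
    ref = profile.reference
    if ref.no_growth:
        raise ValueError("the 0 uM reference shows no growth; cannot classify")

    no_growth = profile.no_growth_concs
    if no_growth:
        return PhenotypeClass(
            kind="complete_inhibition_above_threshold", threshold_conc=no_growth[0]
        )

    thr = rel_change_threshold
    capacity_loss = any(
        (ref.od_max - p.od_max) / ref.od_max >= thr
        for c, p in profile.items()
        if c != 0 and not p.no_growth
    )
    if capacity_loss:
        return PhenotypeClass(kind="capacity_loss")

    lag_shift = any(
        _rel_increase(p.lag, ref.lag) >= thr
        or _rel_increase(p.doubling_time, ref.doubling_time) >= thr
        for c, p in profile.items()
        if c != 0 and not p.no_growth
    )
    if lag_shift:
        return PhenotypeClass(kind="lag_extension")
    return PhenotypeClass(kind="insensitive")
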