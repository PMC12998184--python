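"""Substrate-depletion kinetics and specific activity per g dry weight.

The measurement procedure mirrors how depletion assays are evaluated at the
bench: fit a smooth function to the concentration course, differentiate it
analytically to get the instantaneous depletion rate, pair each rate with the
biomass present at that moment (OD600 times a dry-weight conversion), keep
the initial portion over which rate is proportional to biomass, and report
the proportionality constant as the specific activity

    a = rate / X_DW   [umol L^-1 h^-1 per g L^-1 = umol g_DW^-1 h^-1].

Model selection over a small family (linear, exponential-plus-offset,
logistic decline) is by AIC, with a shape-constrained spline as fallback, so
the choice of functional form is automatic and logged instead of interactive.
Activities whose upper confidence bound falls below a reporting threshold are
flagged as "< threshold" rather than quoted as point estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression

from .params import DEFAULT_BIOMASS_PER_OD
from .timeseries import AssayTimeSeries

__all__ = [
    "BiomassConversion",
    "FittedDepletion",
    "KineticsResult",
    "NitriteDepletionKinetics",
    "fit_concentration_course",
    "instantaneous_rate",
    "rate_vs_biomass",
    "initial_linear_window",
    "specific_activity",
    "classify_below_threshold",
    "summarize_replicates",
]


@dataclass(frozen=True)
class BiomassConversion:
    """OD600 -> dry weight conversion (g dry weight per litre per OD unit)."""

    g_dw_per_l_per_od: float = DEFAULT_BIOMASS_PER_OD

    def __post_init__(self) -> None:
        if not self.g_dw_per_l_per_od > 0:
            raise ValueError("g_dw_per_l_per_od must be > 0")


# ---------------------------------------------------------------------------
# model family


def _linear(t, c0, s):
    return c0 - s * t


def _exp_offset(t, c0, k, b):
    return (c0 - b) * np.exp(-k * t) + b


def _logistic_decline(t, c0, k, t_half):
    return c0 / (1.0 + np.exp(k * (t - t_half)))


class FittedDepletion:
    """A fitted, monotone non-increasing depletion function with a derivative.

    ``rate(t)`` returns the depletion rate -dC/dt (positive when the analyte
    is being consumed); both ``predict`` and ``rate`` refuse extrapolation
    outside the fitted time range.
    """

    def __init__(self, name, params, predict_fn, deriv_fn, domain, rss, n_obs, n_par):
        self.name = name
        self.params = params
        self._predict = predict_fn
        self._deriv = deriv_fn
        self.domain = domain
        self.rss = rss
        self.n_obs = n_obs
        self.n_par = n_par

    @property
    def aic(self) -> float:
        n = self.n_obs
        return n * np.log(self.rss / n + 1e-300) + 2 * self.n_par

    def _check_domain(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        lo, hi = self.domain
        tol = 1e-9 * max(1.0, abs(hi))
        if np.any(t < lo - tol) or np.any(t > hi + tol):
            raise ValueError(f"t outside the fitted range [{lo}, {hi}]")
        return t

    def predict(self, t):
        return self._predict(self._check_domain(t))

    def rate(self, t):
        """Depletion rate -dC/dt in uM per time unit, clipped at 0."""
        return np.clip(-self._deriv(self._check_domain(t)), 0.0, None)


def _try_fit(name, fn, deriv, t, c, p0, bounds, n_par):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(fn, t, c, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError):
        return None
    resid = c - fn(t, *popt)
    return FittedDepletion(
        name=name,
        params=dict(popt_named(name, popt)),
        predict_fn=lambda x, p=popt: fn(x, *p),
        deriv_fn=lambda x, p=popt: deriv(x, *p),
        domain=(float(t[0]), float(t[-1])),
        rss=float(resid @ resid),
        n_obs=t.size,
        n_par=n_par,
    )


def popt_named(name, popt):
    names = {
        "linear": ("c0", "slope"),
        "exp_offset": ("c0", "k", "offset"),
        "logistic_decline": ("c0", "k", "t_half"),
    }[name]
    return zip(names, (float(v) for v in popt))


def _spline_fallback(t, c) -> FittedDepletion:
    # shape-constrained fallback: isotonic (non-increasing) regression of the
    # data, then a monotone PCHIP through the regressed values
    iso = IsotonicRegression(increasing=False).fit(t, c)
    c_mono = iso.predict(t)
    # PCHIP needs strictly increasing x and benefits from deduplicated knots
    pchip = PchipInterpolator(t, c_mono, extrapolate=False)
    dp = pchip.derivative()
    resid = c - c_mono
    return FittedDepletion(
        name="monotone_spline",
        params={},
        predict_fn=pchip,
        deriv_fn=dp,
        domain=(float(t[0]), float(t[-1])),
        rss=float(resid @ resid),
        n_obs=t.size,
        n_par=t.size,
    )


def fit_concentration_course(series: AssayTimeSeries) -> FittedDepletion:
    """Fit the analyte concentration over time with an automatic model choice.

    Censored points are excluded. Candidates are a line, an exponential decay
    toward an offset, and a logistic decline, each constrained to be monotone
    non-increasing; the lowest AIC wins. If no parametric member converges, a
    monotone spline through an isotonic regression of the data is used.
    """
    mask = ~series.censored
    t = series.time[mask]
    c = series.conc[mask]
    if t.size == 0:
        raise ValueError("all points are censored; nothing to fit")
    if t.size < 4:
        raise ValueError("need at least 4 uncensored points to fit")

    c0_guess = float(c[0])
    span = max(float(t[-1] - t[0]), 1e-9)
    drop = max(c0_guess - float(c[-1]), 0.0)
    candidates = []
    f = _try_fit(
        "linear",
        _linear,
        lambda x, c0, s: np.full(np.shape(x), -s),
        t,
        c,
        p0=[c0_guess, drop / span],
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        n_par=2,
    )
    if f:
        candidates.append(f)
    f = _try_fit(
        "exp_offset",
        _exp_offset,
        lambda x, c0, k, b: -(c0 - b) * k * np.exp(-k * x),
        t,
        c,
        p0=[c0_guess, 1.0 / span, min(c)],
        bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
        n_par=3,
    )
    if f and f.params["c0"] >= f.params["offset"]:
        candidates.append(f)
    f = _try_fit(
        "logistic_decline",
        _logistic_decline,
        lambda x, c0, k, th: -c0 * k * np.exp(k * (x - th)) / (1 + np.exp(k * (x - th))) ** 2,
        t,
        c,
        p0=[c0_guess, 2.0 / span, float(np.median(t))],
        bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
        n_par=3,
    )
    if f:
        candidates.append(f)

    if not candidates:
        return _spline_fallback(t, c)
    return min(candidates, key=lambda m: m.aic)


def instantaneous_rate(fit: FittedDepletion, t) -> np.ndarray | float:
    """Depletion rate -dC/dt of the fitted form at time t (uM/h, >= 0)."""
    r = fit.rate(t)
    return float(r) if np.isscalar(t) else r


def rate_vs_biomass(
    fit: FittedDepletion, series: AssayTimeSeries, conv: BiomassConversion
):
    """Pair dry-weight density with depletion rate at each usable timepoint.

    Timepoints after the depletion endpoint (the first censored measurement)
    are excluded: once the analyte is below the detection limit the fitted
    derivative no longer reflects enzymatic turnover. Returns
    ``(x_dw g/L, rate uM/h, time h)`` ordered by time.
    """
    if np.any(~np.isfinite(series.od600)):
        raise ValueError("OD600 must be recorded at every timepoint")
    if series.censored.any():
        terminal = series.time[series.censored].min()
        keep = series.time < terminal
    else:
        keep = np.ones(series.time.shape, dtype=bool)
    t = series.time[keep]
    x_dw = series.od600[keep] * conv.g_dw_per_l_per_od
    rates = fit.rate(t)
    return x_dw, np.asarray(rates, dtype=float), t


def initial_linear_window(
    x_dw,
    rates,
    r2_threshold: float = 0.95,
    min_points: int = 3,
) -> tuple[slice, bool]:
    """Longest initial prefix over which rate is proportional to biomass.

    Proportionality is judged on the residuals of an origin-constrained line
    by the coefficient of determination against the centered variation of the
    rates; a prefix whose rates barely vary relative to their magnitude (the
    resting-cell case, where biomass is constant and rate proportional to it
    means rate constant) passes as trivially linear. The longest prefix
    (>= ``min_points``) that qualifies wins. If none does, the first
    ``min_points`` points are returned with a warning flag.
    """
    x = np.asarray(x_dw, dtype=float)
    y = np.asarray(rates, dtype=float)
    n = x.size
    if n < min_points:
        raise ValueError(f"need at least {min_points} rate/biomass pairs")
    flat_tol = (1.0 - r2_threshold) / 4.0
    for length in range(n, min_points - 1, -1):
        xs, ys = x[:length], y[:length]
        ss_mag = float(ys @ ys)
        ss_tot = float(((ys - ys.mean()) ** 2).sum())
        if ss_tot <= flat_tol * ss_mag:  # includes the all-zero-rates case
            return slice(0, length), False
        s = float(xs @ ys) / float(xs @ xs)
        resid = ys - s * xs
        r2 = 1.0 - float(resid @ resid) / ss_tot
        if r2 >= r2_threshold:
            return slice(0, length), False
    return slice(0, min_points), True


def specific_activity(x_dw, rates, window: slice) -> tuple[float, float]:
    """Origin-constrained slope of rate vs biomass over the window.

    Returns ``(activity, se)`` in umol g_DW^-1 h^-1; the activity is clipped
    at 0 (a rising concentration is no depletion, not negative depletion).
    """
    x = np.asarray(x_dw, dtype=float)[window]
    y = np.asarray(rates, dtype=float)[window]
    if x.size < 2:
        raise ValueError("window must contain at least 2 pairs")
    sxx = float(x @ x)
    if sxx == 0.0:
        raise ValueError("biomass is zero throughout the window")
    s = float(x @ y) / sxx
    resid = y - s * x
    dof = max(x.size - 1, 1)
    se = float(np.sqrt((resid @ resid) / dof / sxx))
    return max(s, 0.0), se


def classify_below_threshold(activity: float, sd: float, threshold: float) -> bool:
    """True when the activity's upper bound (mean + sd) lies strictly below
    the reporting threshold, i.e. the result should be quoted "< threshold"."""
    return (activity + sd) < threshold


def summarize_replicates(
    activities, threshold: float = 1.0
) -> tuple[float, float, bool]:
    """Mean +/- sample sd over replicate assays, with the below-threshold flag."""
    a = np.asarray(list(activities), dtype=float)
    if a.size == 0:
        raise ValueError("no replicate activities given")
    mean = float(a.mean())
    sd = float(a.std(ddof=1)) if a.size > 1 else 0.0
    return mean, sd, classify_below_threshold(mean, sd, threshold)


@dataclass(frozen=True)
class KineticsResult:
    """Frozen summary of one depletion assay."""

    fitted_form: str
    fitted_params: dict
    specific_activity: float
    specific_activity_se: float
    window: tuple[int, int]
    window_flagged: bool
    below_threshold: bool
    threshold: float
    analyte: str
    species: str | None


class NitriteDepletionKinetics(BaseEstimator):
    """End-to-end kinetics estimator: series in, specific activity out.

    Parameters
    ----------
    biomass_per_od : float, default 0.36
        Dry weight (g/L) per OD600 unit.
    r2_threshold : float, default 0.95
        Linearity requirement for the initial rate-vs-biomass window.
    min_window : int, default 3
        Minimum window size; used as fallback (flagged) when no prefix is
        linear enough.
    report_threshold : float, default 1.0
        Activities whose upper bound falls below this are flagged "< threshold"
        (umol g_DW^-1 h^-1).
    lod : float, default 10.0
        Detection limit (uM); points below it are censored before fitting.

    Attributes (after ``fit``)
    --------------------------
    fit_ : FittedDepletion
    biomass_ , rate_series_ , time_points_ : ndarray
        The rate-vs-biomass pairs and their timestamps.
    window_ : slice, window_flagged_ : bool
    specific_activity_ : float, specific_activity_se_ : float
    below_threshold_ : bool
    """

    def __init__(
        self,
        biomass_per_od: float = DEFAULT_BIOMASS_PER_OD,
        r2_threshold: float = 0.95,
        min_window: int = 3,
        report_threshold: float = 1.0,
        lod: float = 10.0,
    ):
        self.biomass_per_od = biomass_per_od
        self.r2_threshold = r2_threshold
        self.min_window = min_window
        self.report_threshold = report_threshold
        self.lod = lod

    def fit(self, series: AssayTimeSeries) -> "NitriteDepletionKinetics":
        series = series.with_lod(self.lod)
        self.fit_ = fit_concentration_course(series)
        conv = BiomassConversion(self.biomass_per_od)
        x, r, t = rate_vs_biomass(self.fit_, series, conv)
        self.biomass_, self.rate_series_, self.time_points_ = x, r, t
        self.window_, self.window_flagged_ = initial_linear_window(
            x, r, self.r2_threshold, self.min_window
        )
        self.specific_activity_, self.specific_activity_se_ = specific_activity(
            x, r, self.window_
        )
        # resolvability guard: the depletion the fit claims within the window
        # must exceed the concentration noise (fit residual rms), otherwise
        # the apparent activity is an artifact (e.g. a slow stationary-phase
        # leak uncorrelated with biomass) and is reported below threshold
        t_w = t[self.window_]
        sigma_c = float(np.sqrt(self.fit_.rss / max(self.fit_.n_obs - self.fit_.n_par, 1)))
        delta_w = float(self.fit_.predict(t_w[0]) - self.fit_.predict(t_w[-1]))
        self.window_depletion_ = delta_w
        self.noise_floor_ = sigma_c
        resolvable = delta_w > 2.0 * sigma_c
        self.below_threshold_ = (
            classify_below_threshold(
                self.specific_activity_, self.specific_activity_se_, self.report_threshold
            )
            or not resolvable
        )
        self._analyte = series.analyte
        self._species = series.species
        return self

    def predict(self, t):
        """Fitted concentration (uM) at times ``t`` within the data range."""
        return self.fit_.predict(t)

    def rate(self, t):
        """Fitted depletion rate (uM/h) at times ``t`` within the data range."""
        return self.fit_.rate(t)

    def result(self) -> KineticsResult:
        return KineticsResult(
            fitted_form=self.fit_.name,
            fitted_params=dict(self.fit_.params),
            specific_activity=self.specific_activity_,
            specific_activity_se=self.specific_activity_se_,
            window=(self.window_.start, self.window_.stop),
            window_flagged=self.window_flagged_,
            below_threshold=self.below_threshold_,
            threshold=self.report_threshold,
            analyte=self._analyte,
            species=self._species,
        )
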