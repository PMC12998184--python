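"""Synthetic incubation assays with known ground truth.

Everything the measurement pipeline consumes can be generated here: growth
curves, analyte-depletion courses driven by biomass, calibration-standard
tables, and counting-chamber/dry-weight observations. The generating
parameters travel alongside the noisy data so recovery can be tested.

Model
-----
Growth is a lag + logistic curve; after the lag the density rises from
``od_initial`` toward ``od_max`` and the *realised* maximum specific growth
rate equals ``mu_max`` (so the doubling time is ln2/mu_max). Depletion obeys

    dC/dt = -a * X(t) * C/(km + C) - k_pH * C,

with ``a`` the specific activity (umol g_DW^-1 h^-1), ``X = OD * biomass_per_od``
the dry-weight density (g/L) and ``k_pH`` the first-order abiotic decay.
Cysteine scavenges a fixed amount of nitrite instantaneously at t = 0.
Measurement noise (multiplicative on OD, additive on concentration and
absorbance) is applied last and is fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .calibration import abiotic_decay_rate, effective_initial_nitrite
from .params import (
    AbioticModelParams,
    ConsumptionModelParams,
    GrowthModelParams,
    NoiseSpec,
)
from .timeseries import AssayTimeSeries

__all__ = [
    "SimulationTruth",
    "SimulatedExperiment",
    "FullyScavengedError",
    "simulate_growth",
    "simulate_depletion",
    "simulate_assay",
    "simulate_calibration_standards",
    "simulate_counting_experiment",
    "simulate_inhibition_profiles",
    "INHIBITION_ARCHETYPES",
    "INHIBITION_DOSES",
]


class FullyScavengedError(ValueError):
    """The nominal analyte dose is entirely scavenged before the assay starts."""


@dataclass(frozen=True)
class SimulationTruth:
    """Generating parameters carried unmodified alongside the noisy series."""

    consumption: ConsumptionModelParams
    abiotic: AbioticModelParams
    c0_effective: float
    growth: GrowthModelParams | None = None


@dataclass(frozen=True)
class SimulatedExperiment:
    series: AssayTimeSeries
    truth: SimulationTruth


def _validate_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must not be empty")
    if np.any(times < 0) or np.any(np.diff(times) <= 0):
        raise ValueError("times must be non-negative and strictly increasing")
    return times


def simulate_growth(params: GrowthModelParams, times) -> np.ndarray:
    """OD600 of a lag + logistic growth curve at the given times (h).

    OD stays at ``od_initial`` through the lag, then follows a logistic rise
    toward ``od_max``. The internal logistic rate is inflated by
    1/(1 - od_initial/od_max) so that the curve's maximum specific growth
    rate (max d ln OD/dt, reached just after the lag) is exactly ``mu_max``.
    """
    times = _validate_times(times)
    p = params
    if p.mu_max == 0 or p.od_max == p.od_initial:
        return np.full(times.shape, p.od_initial)
    r = p.mu_max / (1.0 - p.od_initial / p.od_max)
    dt = np.clip(times - p.lag, 0.0, None)
    # numerically stable logistic: od_max / (1 + ((K-N0)/N0) e^{-r dt})
    ratio = (p.od_max - p.od_initial) / p.od_initial
    return p.od_max / (1.0 + ratio * np.exp(-r * dt))


def simulate_depletion(
    times,
    od600,
    cons: ConsumptionModelParams,
    abiotic: AbioticModelParams,
    c_nominal: float,
    noise: NoiseSpec = NoiseSpec(),
    ph: float | np.ndarray = 7.0,
    mode: str = "resting",
    species: str | None = None,
    analyte: str = "nitrite",
    growth_truth: GrowthModelParams | None = None,
    max_step: float = 0.01,
) -> SimulatedExperiment:
    """Integrate biomass-driven analyte depletion over an OD course.

    The initial concentration is the nominal dose minus the instantaneous
    cysteine loss; the ODE above is then integrated with an explicit adaptive
    stepper capped at ``max_step`` (0.01 h by default) so runs reproduce
    bit-for-bit. The concentration never goes negative; measurement noise is
    added after integration.
    """
    if c_nominal <= 0:
        raise ValueError("c_nominal must be > 0")
    times = _validate_times(times)
    od600 = np.asarray(od600, dtype=float)
    if od600.shape != times.shape:
        raise ValueError("od600 must match times in length")
    ph_arr = np.full(times.shape, float(ph)) if np.isscalar(ph) else np.asarray(ph, dtype=float)

    c0 = effective_initial_nitrite(c_nominal, abiotic.cysteine_mM, abiotic)
    if c0 <= 0:
        raise FullyScavengedError(
            f"nominal {c_nominal} uM fully scavenged by "
            f"{abiotic.cysteine_mM} mM cysteine"
        )

    a, km, bpo = cons.specific_activity, cons.km, cons.biomass_per_od
    k_ph = np.array([abiotic_decay_rate(p, abiotic) for p in ph_arr])

    def rhs(t: float, y: np.ndarray) -> list[float]:
        c = y[0]
        if c <= 0:
            return [0.0]
        x_dw = np.interp(t, times, od600) * bpo
        mm = c / (km + c) if km > 0 else 1.0
        k = np.interp(t, times, k_ph)
        return [-a * x_dw * mm - k * c]

    def depleted(t: float, y: np.ndarray) -> float:
        return y[0]

    depleted.terminal = True  # type: ignore[attr-defined]
    depleted.direction = -1  # type: ignore[attr-defined]

    conc = np.full(times.shape, 0.0)
    if times[0] > 0:
        # integrate from t=0 even when sampling starts later
        t_span = (0.0, times[-1])
    else:
        t_span = (times[0], times[-1])
    if t_span[0] == t_span[1]:
        conc = np.full(times.shape, c0)
    else:
        sol = solve_ivp(
            rhs,
            t_span,
            [c0],
            t_eval=times,
            max_step=max_step,
            rtol=1e-8,
            atol=1e-10,
            events=depleted,
            dense_output=False,
        )
        conc[: sol.y.shape[1]] = sol.y[0]
        conc = np.clip(conc, 0.0, None)

    rng = noise.rng()
    od_meas = od600.copy()
    if noise.od_cv > 0:
        od_meas = od_meas * (1.0 + rng.normal(0.0, noise.od_cv, times.size))
        od_meas = np.clip(od_meas, 1e-6, None)
    conc_meas = conc.copy()
    if noise.conc_sd > 0:
        conc_meas = np.clip(conc_meas + rng.normal(0.0, noise.conc_sd, times.size), 0.0, None)

    series = AssayTimeSeries(
        time=times,
        od600=od_meas,
        conc=conc_meas,
        ph=ph_arr,
        analyte=analyte,
        mode=mode,
        species=species,
    )
    truth = SimulationTruth(
        consumption=cons, abiotic=abiotic, c0_effective=c0, growth=growth_truth
    )
    return SimulatedExperiment(series=series, truth=truth)


def simulate_assay(
    growth: GrowthModelParams,
    cons: ConsumptionModelParams,
    abiotic: AbioticModelParams,
    c_nominal: float,
    times,
    noise: NoiseSpec = NoiseSpec(),
    ph: float = 7.0,
    species: str | None = None,
    analyte: str = "nitrite",
) -> SimulatedExperiment:
    """Convenience: growth curve + depletion in one call (growing culture)."""
    od = simulate_growth(growth, times)
    return simulate_depletion(
        times,
        od,
        cons,
        abiotic,
        c_nominal,
        noise=noise,
        ph=ph,
        mode="growing",
        species=species,
        analyte=analyte,
        growth_truth=growth,
    )


def simulate_calibration_standards(
    levels,
    slope: float = 0.005,
    intercept: float = 0.02,
    noise: NoiseSpec = NoiseSpec(),
) -> pd.DataFrame:
    """Standards table ``conc_uM, absorbance`` for a linear colorimetric assay."""
    levels = np.asarray(levels, dtype=float)
    if slope < 0:
        raise ValueError("slope must be >= 0")
    absorbance = slope * levels + intercept
    if noise.absorbance_sd > 0:
        absorbance = absorbance + noise.rng().normal(0.0, noise.absorbance_sd, levels.size)
    return pd.DataFrame({"conc_uM": levels, "absorbance": absorbance})


#: Nitrite dose levels (uM) used in growth-inhibition experiments.
INHIBITION_DOSES = (0.0, 50.0, 100.0, 200.0, 500.0, 1000.0)

#: Reported effect sizes of the three inhibition archetypes: per dose either
#: (lag h, doubling time h, od_max) or None for complete growth inhibition.
#: * insensitive: parameters flat across doses (lag 5 h, t_d 1.1 h, max 0.6);
#: * lag_extension: t_d 0.74 -> 1.74 h and lag 9 -> 20 h with max OD ~0.75;
#: * complete_inhibition: capacity declines 0.7 -> 0.25 up to 200 uM, no
#:   growth at 500/1000 uM.
INHIBITION_ARCHETYPES: dict[str, dict[float, tuple | None]] = {
    "insensitive": {c: (5.0, 1.1, 0.6) for c in INHIBITION_DOSES},
    "lag_extension": {
        c: (lag, td, 0.75)
        for c, lag, td in zip(
            INHIBITION_DOSES,
            (9.0, 10.0, 11.0, 13.0, 16.0, 20.0),
            (0.74, 0.80, 0.90, 1.10, 1.40, 1.74),
        )
    },
    "complete_inhibition_above_threshold": {
        0.0: (7.5, 0.8, 0.7),
        50.0: (7.5, 0.8, 0.6),
        100.0: (7.5, 0.8, 0.45),
        200.0: (7.5, 0.8, 0.25),
        500.0: None,
        1000.0: None,
    },
}


def simulate_inhibition_profiles(
    noise: NoiseSpec = NoiseSpec(),
    t_end: float = 48.0,
    dt: float = 0.25,
    od_initial: float = 0.05,
) -> dict[str, dict[float, tuple[np.ndarray, np.ndarray]]]:
    """Synthetic growth curves for the three inhibition archetypes.

    Returns ``{archetype: {dose uM: (times, od600)}}``. Curves are observed
    long enough (48 h) for even the slowest dose to reach its plateau, so the
    maximum OD is an asymptote, not a truncation artifact. A ``None`` entry
    in the archetype table produces a flat no-growth curve at ``od_initial``.
    One RNG drawn from ``noise.seed`` covers the whole dataset.
    """
    times = np.arange(0.0, t_end + dt / 2, dt)
    rng = noise.rng()
    out: dict[str, dict[float, tuple[np.ndarray, np.ndarray]]] = {}
    for archetype, doses in INHIBITION_ARCHETYPES.items():
        curves = {}
        for conc, spec in doses.items():
            if spec is None:
                od = np.full(times.shape, od_initial)
            else:
                lag, td, od_max = spec
                od = simulate_growth(
                    GrowthModelParams(
                        od_initial=od_initial,
                        od_max=od_max,
                        mu_max=np.log(2) / td,
                        lag=lag,
                    ),
                    times,
                )
            if noise.od_cv > 0:
                od = np.clip(od * (1.0 + rng.normal(0.0, noise.od_cv, times.size)), 1e-6, None)
            curves[conc] = (times, od)
        out[archetype] = curves
    return out


def simulate_counting_experiment(
    per_cell_dw: float,
    cells_per_l_od: float,
    ods,
    noise: NoiseSpec = NoiseSpec(),
) -> pd.DataFrame:
    """Counting-chamber + dry-weight observations at several OD levels.

    Expected counts and dry weights scale linearly with OD; multiplicative
    noise of coefficient of variation ``od_cv`` is applied independently to
    both observations. Columns: ``od, cells_per_l, dw_g_per_l``.
    """
    ods = np.asarray(ods, dtype=float)
    if ods.size < 2:
        raise ValueError("need at least 2 OD levels for a regression")
    if per_cell_dw <= 0 or cells_per_l_od <= 0:
        raise ValueError("per_cell_dw and cells_per_l_od must be > 0")
    cells = cells_per_l_od * ods
    dw = per_cell_dw * cells
    if noise.od_cv > 0:
        rng = noise.rng()
        cells = cells * (1.0 + rng.normal(0.0, noise.od_cv, ods.size))
        dw = dw * (1.0 + rng.normal(0.0, noise.od_cv, ods.size))
    return pd.DataFrame({"od": ods, "cells_per_l": cells, "dw_g_per_l": dw})
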