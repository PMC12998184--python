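# Methods

This note documents the models implemented in `gutnitro`, their assumptions,
the defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter for
reproducibility. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Units

Time in hours, concentrations in μM (≡ μmol · L⁻¹), optical density at
600 nm (dimensionless), biomass as g dry weight (g_DW) per litre, specific
activity in μmol · g_DW⁻¹ · h⁻¹. All algorithms are unit-agnostic (rescaling
time to minutes with rates rescaled by 1/60 reproduces results exactly; this
is tested), but defaults are stated in these units.

## Synthetic incubation assays

### Growth

Growth curves follow a lag + logistic form: OD is constant at `od_initial`
through the lag, then rises logistically toward `od_max`. The curve is
parameterized by the quantities a growth experiment actually reports — lag
(h), maximum specific growth rate μ_max (h⁻¹, equivalently doubling time
t_d = ln 2 / μ_max), and maximum OD. One deliberate design choice: the
internal logistic rate is set to r = μ_max / (1 − od_initial/od_max), so
that the curve's *realised* maximum of d ln OD/dt (reached just after the
lag) equals μ_max exactly. With the naive parameterization the realised
maximum is r(1 − od_initial/od_max), i.e. a curve generated with "doubling
time 1.1 h" would actually double no faster than every ~1.2 h at typical
inoculum ratios — the stated parameters would not mean what the legend of a
growth figure means. Gompertz and richer forms were rejected: three
parameters plus lag are exactly what the phenotyping reports.

### Depletion

Analyte depletion is biomass-driven with a Michaelis–Menten factor and a
first-order abiotic channel:

    dC/dt = −a · X_DW(t) · C/(k_m + C) − k_pH(pH(t)) · C,

with X_DW = OD(t) · f, f = 0.36 g · L⁻¹ · OD⁻¹ by default. `k_m` is an
artifact knob, not a measured constant: k_m = 0 gives the zero-order
(saturating) regime, the default k_m = 20 μM reproduces both a near-linear
early decline and an exponential tail with one parameter. Cysteine, the
reducing agent anaerobic cultivation cannot do without, scavenges nitrite on
a seconds timescale; this is modeled as an instantaneous loss at t = 0 of
33.3 μM per mM cysteine, anchored so that the standard assay dose (150 μM
nominal, 1.5 mM cysteine) starts at an effective 100 μM. A dose fully
scavenged before t = 0 raises `FullyScavengedError`.

The ODE is integrated with an explicit adaptive stepper (RK45) with the step
size capped at 0.01 h and rtol 1e-8: stiffness is mild, and bit-for-bit
reproducibility matters more than speed. A terminal event stops integration
when C reaches 0, after which the concentration stays exactly 0 (the
Michaelis factor's discontinuity at C = 0 for k_m = 0 is never crossed).

Measurement noise is applied after integration — multiplicative Gaussian on
OD (`od_cv`), additive Gaussian on concentration (`conc_sd`, clipped at 0),
additive on absorbance — and is fully determined by the seed.

### What the generator does not emulate

No HNO₂/NO⁺ speciation, nitrosamine chemistry, multi-compartment transit,
substrate-dependent growth coupling (growth and depletion are one-way:
biomass drives depletion, nitrite does not feed back on growth within one
simulated assay), plate-edge effects, or drift/autocorrelation in the noise.
Passing recovery tests therefore demonstrate that the estimators invert the
stated model at realistic noise, not that real assays contain no systematic
errors beyond it.

## Assay chemistry

Calibration is unweighted OLS of absorbance on concentration over ≥3
distinct standard levels (0–100 μM working range); no weighting scheme is
justified by the data. The inverse map censors estimates below the 10 μM
detection limit (and negative estimates); censored values propagate as an
explicit state rather than 0 or the LOD, so depletion fits can exclude them.
Censoring is monotone in absorbance by construction.

Abiotic decay: at pH ≥ 5.8 a background first-order rate of −ln(0.9)/24 h⁻¹
(~10% loss per 24 h) applies; below pH 5.8 chemical scavenging accelerates
sharply and rates must be supplied as a pH → rate table (interpolated
linearly, entries honoured verbatim), because no tabulated acidic-decay
dataset ships with the package. Valid pH range 3–9. `subtract_abiotic`
multiplies the measured course by exp(∫k dt); this inverts the abiotic
channel exactly for cell-free controls and to first order when enzymatic
depletion is also present.

The slow, near-linear 24 h decline of nitrite with increasing cysteine
(distinct from the seconds-scale drop) is kept in a separate helper
(`cysteine_loss_24h`, 17.5 μM per mM over 24 h) and is not part of the
initial-concentration correction.

## Depletion kinetics and specific activity

The measurement procedure replaces interactive curve fitting with an
automatic, logged model choice: candidates are a line, an exponential decay
to an offset, and a logistic decline, each constrained monotone
non-increasing, selected by AIC (n ln(RSS/n) + 2p). If no candidate
converges, a shape-constrained fallback is used: isotonic (non-increasing)
regression of the data followed by a monotone PCHIP through the regressed
values. Rates are analytic derivatives of the fitted form, sign-flipped and
clipped at 0; extrapolation outside the fitted time range is refused.
Censored points are excluded from fitting, and the first censored timepoint
defines a terminal time after which rates are not evaluated.

The initial linear window is the longest time-ordered prefix of
(X_DW, rate) pairs over which the rate is proportional to biomass, judged by
the R² of an origin-constrained line against the centered variation of the
rates (threshold 0.95, configurable; minimum 3 points, with a warning flag
when even the minimal prefix fails). A prefix whose rates barely vary
relative to their magnitude passes as trivially linear — this is the
resting-cell case, where biomass is constant and proportionality means a
constant rate. Specific activity is the origin-constrained slope over the
window (not a single-point ratio): it uses the whole initial portion and is
robust to one noisy timepoint.

Reporting threshold: activities whose upper bound (estimate + sd) falls
strictly below the threshold (default 1 μmol · g_DW⁻¹ · h⁻¹) are reported as
"< threshold". On top of that the estimator applies a resolvability guard:
the depletion the fitted curve claims *within the window* must exceed twice
the concentration-fit residual rms. This is what defuses the
stationary-phase artifact — a slow late leak uncorrelated with biomass (cell
lysis releasing nitrite-reactive compounds) produces near-zero fitted rates
over the initial window, and whatever tiny activity survives division by the
small early biomass is below the noise floor and flagged, never reported as
a positive activity. Replicates aggregate as mean ± sample sd. Nitrate
series are processed identically; the analyte label only changes reporting.

### Recovery conditions

Monte-Carlo recovery (tests and acceptance script) runs resting-cell
simulations at truths a ∈ {10, 100, 1000, 10 000} μmol · g_DW⁻¹ · h⁻¹ with
2 μM concentration noise, 20 seeds per level, sampling every 0.1 h for
2.4 h. Simulations use the saturating regime (k_m = 0): specific activity is
operationally the initial linear depletion rate per unit biomass, so the
recovery target is the zero-order turnover itself; with k_m > 0 the initial
rate is a · C₀/(k_m + C₀) by construction, a property of the depletion law
rather than of the estimator. The cell density is titrated per level so
depletion takes ~2 h (OD = (50/a)/0.36), mirroring how bench assays adjust
cell densities per organism. These problem sizes keep the full suite and the
acceptance script to seconds.

## Biomass calibration

Thoma-chamber arithmetic: cells · mL⁻¹ = mean count per main square ×
dilution / square volume, with the default square volume 0.0025 mm² ×
0.02 mm = 5 × 10⁻⁸ mL. Dry weight vs cell number is regressed through the
origin — zero cells must mean zero mass, and the physical constraint decides
where the procedure itself does not specify an intercept. Duplicate drying
measurements (24 h/48 h) are averaged, with a flag at >5% discrepancy.
Species without a dry-weight determination are carried in the reference
table but excluded from community averages. The bundled reference table of
13 gut species yields a community-average per-cell dry mass consistent with
2.52 × 10⁻¹³ g (recomputed, not assumed; small deviations reflect the
rounding of the printed per-OD columns).

## Colon extrapolation

All organ-scale numbers are products of the reference constants: total
bacterial count 3.23 × 10¹¹ cells per g dry stool, per-cell dry mass
2.52 × 10⁻¹³ g, colon content 400 mL wet stool at 1.04 g · mL⁻¹ with 75%
water. Abundance is interpreted as a fraction of cell counts and — via the
single shared per-cell mass — of biomass. The bolus clearance time uses
zero-order kinetics at the measured total activity: it is a capacity
argument, not a dynamic model, and conservation (time × activity = amount)
holds exactly. Mixture predictions renormalize abundance weights over the
included taxa, since a partial community is still a valid mixture; the
abundance-weighted prediction from per-species activities agrees with a
measured mixed community only to order of magnitude (dominated by the single
high-activity taxon), and is treated as such. Two slightly different
specific-activity roundings exist for the dominant degrader in the source
material; the extrapolation chain uses the value its own table uses (10 966),
while measurement-level tests use the replicate mean (10 770 ± 2183).

## Growth inhibition

Growth parameters per curve: a centered 3-point moving average smooths the
OD; the maximum specific growth rate is the steepest slope of log OD over a
sliding 5-point window; lag is the tangent-intercept (where that steepest
tangent crosses the initial log OD); od_max is the maximum smoothed OD;
curves rising less than 0.05 OD above baseline are flagged no-growth. The
steepest-window estimate touches the true μ_max only with reasonably dense
sampling (the peak is instantaneous); at 6 min sampling the noise-free bias
is below 2%, at 15 min it can reach ~6%. Classification, which compares
doses against the 0 μM reference, is insensitive to this shared bias.

Phenotype classes use a 25% relative-change threshold against the 0 μM
reference (the source classification is qualitative; 25% separates the three
archetypes cleanly while tolerating their reported SDs), with deterministic
precedence complete inhibition > capacity loss > lag extension >
insensitive, so an organism that both loses capacity and stops growing at
high doses is keyed to the dose where growth ceases. Reference lags below
0.5 h are floored in the denominator of the relative change to keep the
ratio meaningful. Synthetic archetype dose series (0, 50, 100, 200, 500,
1000 μM) are observed for 48 h at 15 min resolution so that even a curve
with a 20 h lag and a 1.74 h doubling time reaches its plateau — otherwise
the maximum OD would be a truncation artifact and a pure lag-extension
phenotype would masquerade as capacity loss.

## Known limitations

* The depletion functional form of real microbial nitrite uptake is unknown;
  k_m is a simulator construct and is deliberately not fit from data.
* `subtract_abiotic` is exact only when enzymatic and abiotic channels do
  not interact (it inverts a pure first-order decay); with both active it is
  a first-order correction.
* The acidic (pH < 5.8) decay channel requires a user-supplied table.
* The colon model has no absorption, secretion, transit or
  enterosalivary-circulation component; it is a static capacity model.
* Censored (below-LOD) values are excluded rather than treated by censored
  regression; with the default 10 μM LOD and 100 μM initial dose this
  discards little information.
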