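# gutnitro

Quantifying how the human gut microbiota detoxifies nitrite and nitrate.

Dietary and endogenously recycled nitrate ends up as nitrite (NO₂⁻) in the
gastrointestinal tract, where it can nitrosate secondary amines into
carcinogenic N-nitroso compounds. Gut bacteria — above all *Escherichia coli*
and other Enterobacteriaceae, plus *Bacteroides*/*Phocaeicola* species and
several small-intestinal lactobacilli and veillonellae — reduce nitrite
enzymatically to ammonia or NO, keeping the steady-state concentration below
detection. `gutnitro` is a Python toolkit for the quantitative side of that
story: it turns incubation time series (OD₆₀₀, analyte concentration, pH)
into **specific activities** in μmol · g_DW⁻¹ · h⁻¹, and scales them up to the
detoxification capacity of a whole colon. It is aimed at microbial
physiologists and microbiome researchers who run substrate-depletion assays
and want a reproducible, scriptable version of the usual spreadsheet chain.

## What it computes

**Kinetics.** For an assay time series the pipeline fits the concentration
course C(t) (linear, exponential-plus-offset, or logistic decline, chosen by
AIC, with a monotone-spline fallback), differentiates it analytically, pairs
the depletion rate −dC/dt with the biomass density X_DW = OD₆₀₀ · f (with
f = 0.36 g · L⁻¹ · OD⁻¹ by default), finds the initial window where rate ∝
X_DW, and reports the origin-constrained slope

  a = (−dC/dt) / X_DW   [μmol · L⁻¹ · h⁻¹ per g · L⁻¹ = μmol · g_DW⁻¹ · h⁻¹].

Activities that the assay cannot resolve (upper confidence bound below a
reporting threshold, or window depletion below the noise floor) are flagged
"< threshold" instead of being quoted as numbers.

**Assay chemistry.** Colorimetric (Griess/Lunge-type) calibration by OLS on
standards, inversion of absorbance at 540 nm to concentration with a 10 μM
detection limit (censored values propagate explicitly, never as 0), the
instantaneous cysteine scavenging correction (150 μM nominal + 1.5 mM
cysteine → 100 μM effective), and removal of the pH-dependent first-order
abiotic decay.

**Biomass calibration.** Thoma-chamber counts → cells · mL⁻¹, dry weight vs
cell number regressed through the origin → per-cell dry mass, averaged over
13 gut species to 2.52 × 10⁻¹³ g · cell⁻¹.

**Colon extrapolation.** abundance × 3.23 × 10¹¹ cells · g_dry-stool⁻¹ →
cells/g → biomass/g → dry-stool activity → total colonic activity (colon dry
mass = 400 mL × 1.04 g · mL⁻¹ × 25% solids = 104 g), plus bolus clearance
times and abundance back-estimation.

**Growth inhibition.** Lag, doubling time and maximum OD per nitrite dose,
classified into insensitive / lag-extension / capacity-loss / complete
inhibition phenotypes.

**Synthetic data.** Every input can be generated with known ground truth
(lag + logistic growth, Michaelis–Menten-type depletion ODE, measurement
noise, seeded), so the whole pipeline is testable offline.

## Worked example

Simulate a resting-cell assay at an *E. coli*-scale truth of
10 770 μmol · g_DW⁻¹ · h⁻¹ with 2 μM measurement noise, re-measure it, and run
the organ-scale chain:

```python
import numpy as np
from gutnitro import (AbioticModelParams, ConsumptionModelParams,
                      NitriteDepletionKinetics, NoiseSpec, StoolPhysiology,
                      TaxonProfile, activity_chain, bolus_amount, detox_time,
                      simulate_depletion, BolusScenario)

times = np.arange(0.0, 2.45, 0.1)
cons = ConsumptionModelParams(specific_activity=10770.0, km=0.0)
od = np.full(times.shape, (50.0 / 10770.0) / 0.36)   # depletion in ~2 h
exp = simulate_depletion(times, od, cons,
                         AbioticModelParams(background_decay_per_h=0.0),
                         c_nominal=150.0,
                         noise=NoiseSpec(conc_sd=2.0, seed=0), mode="resting")
est = NitriteDepletionKinetics().fit(exp.series)
print(exp.truth.c0_effective, est.fit_.name, round(est.specific_activity_))

ecoli = TaxonProfile("Escherichia coli", abundance=0.008, specific_activity=10966.0)
res = activity_chain(ecoli, StoolPhysiology())
amount = bolus_amount(BolusScenario())
print(res.dry_stool_activity, res.total_activity, detox_time(amount, res.total_activity))
```

This prints (seed 0):

```
100.0 linear 11002
7.140708287999999 742.6336619519999 1.6158707334189788
```

i.e. the 150 μM dose is scavenged to an effective 100 μM, the fitted course
is linear (zero-order), the recovered activity is 11 002 μmol · g_DW⁻¹ · h⁻¹
(truth 10 770, 2.2% off at this noise level), and at 0.8% abundance that
organism alone clears a 20 μmol nitrite bolus from the colon in about
1.6 minutes (742.6 μmol · h⁻¹ total activity, 7.14 μmol · g_dry-stool⁻¹ · h⁻¹).

A CLI mirrors the library: `gutnitro simulate assay`, `gutnitro kinetics
fit`, `gutnitro biomass calibrate`, `gutnitro colon extrapolate|detox`,
`gutnitro growth classify` (all accept `--help`).

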