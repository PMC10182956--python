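# steatox

A tested, reusable pipeline for quantifying chemically induced liver
steatosis from multi-channel high-content imaging, and for translating
the resulting in vitro bioactive concentrations into human oral dose
estimates.

The package is aimed at in vitro toxicologists and new-approach-method
developers who screen hepatotoxicants in HepaRG-like cultures. It covers
the full chain:

1. **Imaging** — four-channel fluorescence fields (Hoechst nuclei,
   Bodipy lipid droplets, Mitotracker mitochondrial membrane potential,
   CellROX oxidative stress) are segmented (Otsu nuclei with a
   10–100 px equivalent-diameter filter and watershed declumping,
   top-hat-enhanced droplet detection, intensity-guided propagation of
   cell borders from nucleus seeds) and quantified per well. Apoptotic
   nuclei are classified by a random forest trained after undersampling
   the majority class to a 67:33 ratio.
2. **Endpoints** — per-well values (droplets/cell, net Mitotracker and
   CellROX intensity per cell, apoptotic fraction) are normalized per
   plate to the vehicle mean, giving fold changes with vehicle = 1.
   Each chemical × endpoint series is fitted with 3- and 4-parameter
   log-logistic models

   f(x) = c + (d − c) / (1 + exp(b·(ln x − ln e)))

   selected by AIC, and a directional hit is called when the fitted
   curve crosses ±2 pooled SD of the responses at the two lowest tested
   concentrations.
3. **Benchmark concentrations** — positive series are refitted with a
   continuous model suite (exponential 2–5, Hill, linear, polynomial,
   power; normal/log-normal errors; constant or power-of-mean
   variance). The BMC is the concentration at which the fitted mean
   shifts by one control SD (the benchmark response), with a 95%
   profile-likelihood interval; recommended models (converged,
   goodness-of-fit p ≥ 0.1, |scaled residuals| < 2, BMC/BMCL < 20) are
   averaged.
4. **IVIVE / reverse dosimetry** — a three-compartment steady-state PK
   model gives the blood concentration under constant daily oral dosing,

   Css = ko / (GFR·fup + Q·fup·Cl / (Q + fup·Cl/R_b2p)),

   with Q the summed liver + gut blood flow and Cl the whole-body
   metabolic clearance scaled from the in vitro intrinsic clearance
   (1.05 g/ml liver, 1.1×10⁸ hepatocytes/g, species liver volumes).
   Because Css is linear in dose rate, the oral equivalent dose is
   OED = BMC / Css(1 mg/kg/day), draw-wise over a Monte Carlo
   population (1000 individuals with truncated-normal variability in
   GFR, liver/gut flow and clearance). BMC-vs-Css ratios flag potential
   in vivo hazards.
5. **Single cell** — feature matrices are cleaned of constant/missing
   columns, gated into hepatocyte-like (< 5000 px² cytoplasm) and
   cholangiocyte-like (> 5000 px²) populations, reduced by standardized
   PCA, and summarized per subpopulation with notched-boxplot
   statistics.

A first-class synthetic-data module (`steatox.synth`) generates image
scenes, plate datasets, single-cell matrices and PK truth sets with
known ground truth, so every stage is testable without raw plates.

## Worked example

Simulate a 2.3-fold lipid-accumulation inducer (inflection 100 µM)
across 3 experiments × 6 replicates on an 8-point series, call the hit,
derive its BMC, and extrapolate to a human oral equivalent dose:

```python
import numpy as np
from steatox.synth import (ChemicalProfile, CurveParams,
                           generate_plate_dataset, normalize_plate_wells)
from steatox.endpoints import fit_dose_response, compute_hit_threshold, call_hit
from steatox.bmc import fit_bmc_suite
from steatox.ivive import ChemicalPK, simulate_css_distribution, calc_oed

profile = ChemicalProfile(
    "oleate_palmitate",
    {"lipid_accumulation": CurveParams(b=-1.0, c=1.0, d=2.3, e=100.0)},
    tuple(np.geomspace(1.0, 1000.0, 8)))
wells, _ = generate_plate_dataset([profile], replicates=6, experiments=3,
                                  noise_sd=0.05, seed=11)
series = normalize_plate_wells(wells).rename(
    columns={"lipid_accumulation": "fold_change"})

fit = fit_dose_response(series)
lo, hi = compute_hit_threshold(series)
call = call_hit(fit, (lo, hi), (1.0, 1000.0))

bmc_input = series.rename(columns={"fold_change": "response"})
result, fits = fit_bmc_suite(bmc_input[["concentration", "response"]],
                             compute_ci=False)

chem = ChemicalPK("oleate_palmitate", fup=0.05, clint=30.0,
                  r_blood2plasma=1.0, mw=280.0)
css = simulate_css_distribution(chem, ko=1.0, n=1000, seed=0)
oed = calc_oed(result.bmc, css, endpoint="lipid_accumulation")
```

This prints (via the obvious f-strings):

```
fitted top asymptote: 2.26  inflection: 99.0 uM (3-parameter model)
hit threshold: (0.936, 1.102)  hit: True (increase) at >= 9.9 uM
BMC: 4.3 uM from 4 recommended models
median Css at 1 mg/kg/day: 0.64 uM
median OED: 6.8 mg/kg BW/day
```

Reading: the fit recovers the simulated effect (top 2.26 vs truth 2.3,
inflection 99 vs 100 µM); the curve exceeds the ±2 SD band from
~10 µM, so the chemical is a lipid-accumulation hit; the benchmark
response of one control SD is reached at 4.3 µM — far below the
inflection, as expected for a tight control band; and a person would
need ~7 mg/kg/day of this (hypothetical, slowly cleared) chemical for
predicted steady-state blood levels to reach that in vitro
concentration.

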