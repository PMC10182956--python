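# Methods

This note documents the models, default parameters, numerical choices
and known limitations of the steatox pipeline, stage by stage.

## Imaging

**Nucleus segmentation.** Global two-class Otsu thresholding on the
Hoechst channel, hole filling, then declumping of touching nuclei by
watershed on a Gaussian-smoothed (σ = 2 px) Euclidean distance
transform with peak markers at least 10 px apart. Objects are filtered
by *equivalent diameter* 2·√(area/π) to the range 10–100 px; which
diameter definition the original workflow used is not recorded, so the
area-equivalent one is our documented choice, applied in raw image
pixels. The filter is a pure function of object geometry, hence
idempotent. A constant (blank) image yields zero objects rather than an
error.

**Lipid droplets.** The upstream workflow deconvolved the lipid channel
with unpublished settings before thresholding; here the enhancement
step is a white top-hat with a disk of radius 6 px (swappable via
`SegmentationSettings.droplet_enhancement`), which suppresses the broad
cell-body background while preserving droplet-scale peaks. The
top-hat image is Otsu-thresholded with an additional prominence floor
of 25% of the channel's dynamic range — without the floor, faint
top-hat residue at cell edges in droplet-free wells is thresholded
into spurious objects. Objects under 4 px² are discarded. Droplet radii
in the generator (2–4 px) sit safely below the top-hat radius; droplets
larger than the structuring element would be suppressed, a documented
limit of the enhancement choice.

**Cell borders.** Cytoplasm is assigned to nucleus seeds by
intensity-guided propagation, implemented as a watershed over the
inverted Mitotracker intensity restricted to the channel's Otsu
foreground, with a small compactness term (0.01) for tie-breaking.
Bright mitochondrial staining is a low barrier, so borders fall in dim
valleys between cells; with a uniform channel the assignment
degenerates to the nearest-seed geodesic partition. Every foreground
pixel belongs to exactly one cell (partition property).

**Well quantification.** Mean Mitotracker/CellROX intensity over the
cell foreground minus background, where background is the median
intensity outside the cell mask dilated by 5 px (the background
definition was not published; the dilated-median is robust to halo
bleed). Wells with zero cells are flagged invalid and excluded from
normalization rather than imputed.

**Apoptosis classifier.** Per-nucleus intensity/size/shape/texture
features (area, perimeter, eccentricity, solidity, extent, axis
lengths, intensity statistics, 16-bin histogram entropy, fragment
count, and the circularity-based irregularity score P²/4πA). A label
may cover several fragments of one apoptotic nucleus; shape descriptors
are computed on the union so fragmentation lowers solidity and raises
irregularity. The majority class is randomly undersampled to 67:33
(retained majority = round(n_minority·67/33)), a 200-tree random forest
is trained on 75% of the retained nuclei, and accuracy is assessed on a
stratified 25% hold-out (the original assessment was user-defined
visual review, which has no offline equivalent). Training warns below
80% hold-out accuracy, the bottom of the workflow's target band.

## Endpoints and hit calling

Per-well raw endpoints: droplets/cell, (mean − background) Mitotracker
and CellROX intensity per cell, apoptotic fraction. Fold changes are
raw values divided by the same plate's vehicle mean, so a
multiplicative plate effect cancels exactly and vehicle wells average
1 by construction. If a vehicle mean is zero (e.g. no apoptotic cells
in controls), the endpoint falls back to an additive shift centred at 1
with a log entry.

The hit threshold is m ± 2s where m and s are the mean and pooled
(ddof = 1) SD of all replicate wells at the two lowest *nonzero* tested
concentrations; vehicle wells are handled by the fold-change definition
and do not enter the anchors. Centring on the anchor mean rather than
fixing m = 1 tolerates mild low-dose trends.

Log-logistic fits use bounded least squares (trust-region reflective,
analytic Jacobian) over b ∈ [−50, 50], asymptotes within the data span
± one span, and ln e within the tested range extended 10× both ways —
the extension prevents runaway inflection estimates on weak responses.
The 3-parameter variant fixes the baseline asymptote c at 1 (the
vehicle fold change). AIC uses the Gaussian log-likelihood with the
estimated residual variance; ties within 2 AIC units go to the
3-parameter model for parsimony. A finite bounded solution that merely
hits the evaluation cap is treated as converged (common for near-flat
series where the slope runs along its bound); only a fit with no finite
solution raises, so a series is reported unfit rather than silently
flat. Hits are read off a 1024-point log grid over the tested range.

The viability EC50 uses the same machinery; when the fitted curve never
reaches half of its baseline within the tested range the EC50 is
reported right-censored (> top tested) rather than extrapolated.

Validation sensitivity/specificity are computed from aligned expected
vs observed call tables, per endpoint and pooled; pairs present in only
one table are excluded with a log entry.

## Benchmark concentrations

Maximum-likelihood fits of exponential models 2–5, Hill, linear,
polynomial (degree ≤ 3) and power means under normal or log-normal
errors (log-normal models the response median) with constant
(σ² = α) or power-of-mean (σ² = α·μ^ρ) variance. Optimization is
Nelder-Mead from moment-based starts polished by L-BFGS-B under box
bounds (power and exponential shape exponents in [1, 18], Hill
coefficient in [0.5, 18]). Goodness of fit is a likelihood-ratio test
against the saturated per-group-means model with the matching variance
structure; scaled residuals are group-mean deviations over SE.

The benchmark response is a change of one control SD. By default the
*modeled* control SD (√α, or √(α·μ₀^ρ)) defines the BMR — treating the
sample control SD as a fixed constant ignores its sampling noise and
collapsed interval coverage to ~24% in linear simulations, versus ~94%
with the modeled SD profiled jointly. An explicit sample SD can still
be passed for closed-form checks (linear mean 1 + 0.1x with SD 0.2
gives BMC = SD/slope = 2.0 exactly). The BMC is found by scanning a
4096-point log grid to 10× the top tested dose and refining the first
crossing with Brent's method; an unreached BMR is reported
not-computable.

Confidence intervals are 95% profile likelihood: candidate BMC values
are fixed through an SLSQP equality constraint (mean shift at the
candidate equals one modeled control SD) and the χ²₁ cutoff is located
by geometric expansion plus bisection. If a side fails to profile, a
200-draw parametric bootstrap supplies it; a side that never crosses is
reported one-sided with a flag.

Recommendation rules (a documented subset of the usual continuous
benchmark-dose screening logic): converged with computable BMC,
goodness-of-fit p ≥ 0.1, |scaled residual| < 2 at the control and
near-BMC dose groups, and BMC/BMCL < 20. Recommended BMCs — and their
interval bounds — are combined by unweighted arithmetic mean. With no
recommendation, the lowest-AIC usable BMC is reported advisory with the
failing reasons. A BMC above the tested range is flagged extrapolated.

## IVIVE

Three-compartment steady-state model for oral exposure with documented
hard-coded assumptions: constant daily dose rate, 100% bioavailability,
renal excretion via GFR·fup only, well-stirred hepatic elimination
through the combined liver + gut flow, first-order kinetics.
Population-mean flows are allometric — GFR 5.17, liver flow 59.9, gut
flow 47.5 ml/min/kg^3/4 — and converted to whole-body L/day at a
configurable reference body weight (70 kg human; 0.25 kg rat, 2.5 kg
rabbit), making the scaling convention explicit rather than implicit in
an external package. Intrinsic clearance (µl/min/10⁶ hepatocytes)
scales to whole-body clearance through liver density 1.05 g/ml,
1.1×10⁸ hepatocytes/g and species liver volume (human 0.0245, rat
0.0349, rabbit 0.04 L/kg); the forward and inverse conversions are
exact inverses (1 L/h/kg human ↔ 5.89 µl/min/10⁶ cells).

Population variability: the source of the original simulations keeps
its Monte Carlo distributions internal, so the population model here is
explicit and configurable — independent truncated normals (floored at
the 2.5th percentile, keeping draws positive) with default CV 0.3 for
GFR and flows and 0.5 for a multiplicative clearance factor, n = 1000
individuals. Under these defaults the Css median is stable to ~1% CV
across seeds at n = 1000.

OED = BMC/Css(1 mg/kg/day) draw-wise, valid only under the linearity
assumption (asserted: the Css distribution must have been simulated at
ko = 1). Pooling across endpoints is concatenation of draw vectors.
Hazard screening compares BMC with the median predicted Css: ratio < 1
flags a hazard, [1, 10) is near-margin (a ratio of exactly 1 lands
here by the documented tie rule), ≥ 10 is low priority; thresholds are
configurable. Forward-dosimetry evaluation reports R², RMSE and fold
errors on the log10 scale.

## Single cell

Cleaning drops constant feature columns, then columns with > 5%
missing values, then rows with any remaining missing value (metadata
columns are never treated as features); the procedure is idempotent and
reports what was dropped. Cell-type gating thresholds cytoplasm area at
5000 px² — the published wording leaves the boundary value unassigned,
and the documented tie rule sends exactly-5000 px² cells to the
hepatocyte class. PCA standardizes features to zero mean and unit
variance first (the feature families span very different numeric
ranges), caps components at the matrix rank, and fixes component signs
so each loading vector's largest-magnitude entry is positive, making
the decomposition bit-for-bit reproducible. Subpopulation summaries
report median, quartiles and the conventional notch
median ± 1.58·IQR/√n.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure* the analysis
assumes, not microscope physics. Scenes are discs with Gaussian edge
blur (σ = 1 px) on 16-bit canvases: hepatocyte-like cells with
~3000 px² cytoplasm, cholangiocyte-like with ~8000 px², nucleus
diameters 16–24 px, Poisson(4) droplets of radius 2–4 px placed without
overlap, apoptotic nuclei rendered as 2–5 disc fragments on an inner
ring (fragment count is our choice; the defining feature is
morphological fragmentation). There is no PSF, chromatic or shading
model, so segmentation exactness on these scenes demonstrates pipeline
correctness, not robustness to real optics.

Plate simulations follow the study design of 3 independent experiments
× 6 technical replicates per concentration on 8-point series, with a
2.3-fold top effect as the realistic reference effect size. The plate
effect is a single multiplicative log-normal factor per plate
(σ = 0.1 log units) — the normalization's cancellation target — and
well noise is additive Gaussian. The well-level noise SD is not stated
in the source material; the default 0.05 was chosen once as a
realistic imaging-assay CV and makes hit-calling tests meaningful
(null false-hit rate ≤ 10%, hits monotone in effect size). Single-cell
matrices carry ~60 features in the measured families rather than 800+;
the area gate, the two populations, and the "protected subpopulation"
(large-droplet cells with lower oxidative-stress signal) are preserved.
PK truth sets draw fup log-uniform on [0.005, 1] and Clint log-uniform
on [0.1, 200] µl/min/10⁶ cells, with the simulated "in vivo" Css
perturbed by 0.69 decades of log-normal error — the scale of forward
dosimetry error the method reports (≈4.9-fold).

All generators draw from one explicitly passed seeded generator; fixed
seeds give bit-identical outputs.

## Problem sizes and test design

Simulation-based tests run at fixed sizes chosen as the package's own
verification scale: 200 replicates for log-logistic parameter recovery
and forward-dosimetry error recovery, 500 for BMC interval coverage,
1000 for the null false-hit rate, 100 per family for model-family
recommendation. The family-recommendation property is checked with the
normal/constant-variance arm of the suite; the property under test is
family discrimination, which the distribution/variance axes do not
affect, and the full 36-spec suite is exercised separately by the
suite-level tests.

## Known limitations

* No deep-learning or gradient-based segmentation; heavily overlapping
  cells beyond what watershed declumping resolves are out of scope.
* Texture features are a compact fixed set, not a reproduction of any
  specific feature bank's numerics (names and semantics, not values).
* The BMC suite implements a documented subset of benchmark-dose
  screening guidance, not the full decision tree, and no Bayesian model
  averaging.
* The PK model is steady-state only — no time-resolved PBPK, no
  metabolite tracking, and population variability is a parametric
  stand-in rather than a demographic simulator.
* OEDs inherit every IVIVE assumption (nominal = free concentration,
  complete absorption, renal + hepatic clearance only); they are
  screening-level estimates, not risk values.
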