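# Methods

This note documents the models, conventions and numerical choices behind
`metaboflux`, what the synthetic generators do and do not emulate, and the
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Extracellular-flux analysis

A stress-test trace is a time-ordered sequence of per-well rate
measurements (OCR in pmol O₂/min, ECAR in mpH/min) with 1-based
measurement indices. Injections partition the trace into phases: each
measurement is labeled `baseline` or the name of the most recent
preceding injection. All parameters are computed on segmented traces,
optionally protein-normalized (per µg, BCA-style) first; protein
normalization commutes with every difference-based parameter.

Where a single "measurement after an injection" must be chosen from a
phase, the package uses a consistent extremal convention: the **minimum**
within the phase for inhibitor injections (oligomycin, rotenone/antimycin
A, UK5099, etomoxir) and the **maximum** for stimulation phases (FCCP,
glucose). "Before an injection" always means the last measurement of the
preceding phase. Single extremal measurements (not phase means) are used
throughout. Parameter definitions:

| parameter | definition |
|---|---|
| non-mitochondrial respiration | min OCR in rot/AA phase |
| basal respiration | last baseline OCR − non-mito |
| proton leak | min oligomycin-phase OCR − non-mito |
| ATP-linked respiration | basal − leak |
| maximal respiration | max FCCP-phase OCR − non-mito |
| spare respiratory capacity | 100 × maximal / basal (%) |
| OCR/ECAR | first OCR / first ECAR |
| non-glycolytic acidification | last baseline ECAR |
| glycolysis | max glucose-phase ECAR − non-glycolytic |
| glycolytic capacity | max oligomycin-phase ECAR − non-glycolytic |
| glycolytic reserve | capacity − glycolysis (signed) |
| basal glycolysis | last glycoPER before rot/AA |
| compensatory glycolysis | max glycoPER in rot/AA phase |
| mitoOCR/glycoPER | (last OCR before rot/AA − min OCR after) / basal glycolysis |
| %PER from glycolysis | 100 × basal glycolysis / basal PER |
| inhibitor-dependent respiration | last OCR before event − min OCR in event phase |

The proton efflux conversion is PER = ECAR × buffer_factor ×
chamber_volume × volume_scaling and glycoPER = PER − ccf × OCR. The four
constants are configurable (`PerConversion`); the defaults (2.6 mmol/L/pH,
2.28 µL, 1.6, ccf 0.61) are the conventional analyzer values for a
standard assay medium, and a neutral preset (scale 1, ccf 0) exists so
unit tests do not depend on vendor constants.

Undefined ratios (spare capacity with basal ≤ 0, mitoOCR/glycoPER with
non-positive basal glycolysis, OCR/ECAR with zero ECAR, fold change with
zero control, …) are returned as a flagged `Undefined` value — a NaN
subclass carrying a reason string — never a silent NaN.

**Acute-injection fold change.** Each well's response is (mean value in the
injection's phase) / (mean of all pre-injection measurements). Each plate
is one biological experiment: technical wells of a group are averaged to
one biological value before the cross-group ratio, and the reported fold
change is mean(treated biological responses) / mean(control biological
responses). Wells with a zero pre-injection mean are excluded with a
warning.

## Plate simulator

`simulate_plate` draws value(t) = baseline × phase_multiplier ×
(1 + drift·t) + N(0, noise_sd), clipped at zero (rates are nonnegative),
with per-well protein drawn once per well (Gaussian, floored just above
zero). Additive Gaussian noise is the simplest model consistent with
mean ± SD instrument summaries. The simulator does not model oxygen
diffusion, well-edge effects, temperature drift or outlier injection
failures; passing recovery tests therefore demonstrates correctness of
the parameter arithmetic on idealized traces, not robustness to raw
machine artifacts.

Presets encode the study scenarios. `lps_acute`: a single LPS injection,
treated-group ECAR multiplier 1.5 (the one published in-text magnitude)
and OCR multiplier 0.8, next to a flat control group; default 2 wells per
group, 3 measurements per phase at 6.5-minute intervals, noise at 5% of
each channel baseline (OCR 100 → sd 5, ECAR 20 → sd 1). `control`,
`polyic`, `il33_treatment`, `il33_kd`, `il33_oe`: full mitochondrial
stress-test schedules where only the directions of the shifts are
anchored (poly(I:C) and IL-33 raise, IL-33 knockdown lowers, the
FCCP-phase maximal-respiration multiplier; knockdown also raises the
glucose-phase ECAR response). The control stress-test multipliers
(oligomycin 0.45, FCCP 1.5, rot/AA 0.18) are typical healthy-cell
responses; treatment magnitudes are directional choices, not published
numbers, since those values appear only in figures. Biological repeats
are simulated as independent plates with seeds spawned from one root
seed (`simulate_experiments`).

## Natural-abundance correction

A measured spectrum is modeled as C·x where x is the true MID and column
j of C is the mass-shift distribution of a species with j tracer-derived
carbons (each ¹³C with probability `tracer_purity`, default 0.99) and
n − j other carbons (each ¹³C with natural probability `p13_natural`,
default 0.0107). Both constants are configurable; the defaults are
standard textbook values, not instrument-specific calibrations. Because
only carbon isotopes are corrected, the total shift never exceeds n and
every column sums to exactly one (no truncation loss). Correction solves
the system by nonnegative least squares and renormalizes to sum one —
NNLS suppresses the small negative fractions a direct inverse produces on
noisy spectra. The forward operation (`apply_natural_abundance`) uses the
same kernel, making forward-then-correct an identity to solver precision
(fuzz-tested to 1e-6). H/N/O/Si derivatization correction is a documented
limitation: inputs are assumed to be carbon-backbone spectra.

"Relative abundance" splits a pool as unlabeled = M+0 fraction and
labeled = 1 − M+0 (not per-isotopolog), normalized to protein.

## Label-propagation model

The isotope simulator is an isotopic steady-state model (the tracer pulse
is long relative to pool turnover; no kinetics). Pyruvate is M+3 with
probability q = f_glc_labeled × (1 − pyr_dilution), else M+0; lactate
mirrors pyruvate.

Mixture weights are **flux ratios**, so the surrogate ratios respond to
the fluxes they are surrogates for:

- the citrate-synthase acetyl influx is φ_PDH pyruvate-derived (M+2 iff
  the source pyruvate was M+3) and 1 − φ_PDH from unlabeled fuels
  (fatty-acid/ketone oxidation), giving P(acetyl labeled) = q·φ_PDH;
- fresh OAA influx mixes PC-derived OAA (weight φ_PC; M+3 iff source
  pyruvate M+3; the fixed CO₂ is assumed unlabeled) with unlabeled
  anaplerotic influx (weight u_anaplerotic·(1 − φ_PC)), giving
  P(fresh OAA = M+3) = q·φ_PC / (φ_PC + u_anaplerotic·(1 − φ_PC));
- the total OAA pool is cycling_weight recycled malate plus
  1 − cycling_weight fresh influx.

With u_anaplerotic = 1 and no recycling, citrate M+2 = q·φ_PDH·(1 −
q·φ_PC) and citrate M+3 = (1 − q·φ_PDH)·q·φ_PC — plain products of the
configuration fractions, used as an exact closed-form check. Under this
parameterization citrate M+2 / pyruvate M+3 is strictly increasing in
φ_PDH and citrate M+3 / pyruvate M+3 increasing in φ_PC at low cycling,
which is the qualitative content of the PDH/PC surrogate logic.

Positions within a moiety are treated as exchangeable: each TCA
decarboxylation removes a labeled carbon with probability (labeled
count)/(moiety size), and both decarboxylations draw from the OAA-derived
moiety. This avoids 64-state positional bookkeeping while preserving the
mass-level (M+2/M+3) logic; the Monte-Carlo oracle samples molecules
under the same rules, so solver-vs-oracle agreement bounds only the
numerical solution, not this shared approximation. Downstream:
α-ketoglutarate = acetyl ⊗ (OAA − 1 loss); succinate/fumarate/malate =
acetyl ⊗ (OAA − 2 losses); aspartate mirrors OAA; glutamate is a
glu_exchange : (1 − glu_exchange) mixture of α-KG and an unlabeled pool.
Succinate's symmetry is automatic at mass resolution. Reductive
carboxylation is not modeled.

The OAA distribution is solved by fixed-point iteration from the fresh
mixture; the map is a linear contraction with factor cycling_weight, so
the residual decreases geometrically; iteration stops below `tol`
(default 1e-12, max 1000 iterations, error on non-convergence). The
Monte-Carlo oracle keeps a population of molecules and iterates the
recycling mixture until the initial condition is forgotten
(cycling_weight^k < 1e-6, capped at 500); defaults: f_glc_labeled 1.0
(fully labeled glucose medium), pyr_dilution 0.2, φ_PDH 0.6, φ_PC 0.15,
u_anaplerotic 0.5, cycling_weight 0.2, glu_exchange 0.6 — plausible
mid-range values for oxidative epithelial cells; the dilution and
anaplerotic fractions are free parameters, not measured quantities.

## Morphometry

Areas are absolute shoelace areas (shapely), averaged over the 1–3
provided tracings; the diameter is the Feret (max pairwise vertex)
distance of the first tracing. Self-intersecting or zero-area tracings
are rejected by name. Coordinates are continuous, calibrated nm — pixel
grids and scale-setting are upstream concerns.

Class assignment replaces expert judgment with the elongation statistic
e = diameter / (2√(area/π)): e < 1.3 → fragmented, e ≥ 2.5 →
long_tubular, otherwise short_tubular (boundaries round up; cutoffs
configurable and echoed in every output table). The synthetic generator
draws ellipses with class aspect ratios 1 / 3 / 9 — elongations ≈ 1,
1.73, 3, each well inside its band — with lognormal size variation,
3% multiplicative radial jitter (star-shaped, hence always simple),
random rotation and translation, at 64 vertices (polygon area within
0.2% of the true ellipse). Agreement between generated labels and the
classifier is therefore expected ≥ 95% at moderate jitter; heavily
deformed real mitochondria need not respect the ellipse geometry, so the
cutoffs are conventions to be reported, not biological truths. Whether a
study's "diameter" is a Feret or a width measurement is an upstream
ambiguity; the Feret choice is flagged in output metadata.

## Replicates, statistics, reporting

Technical wells (within one experiment) are averaged to one biological
value per (experiment, condition) — a single well passes through — and
only biological values enter tests or cross-group ratios. Aggregation is
idempotent. Tables report mean ± SD for technical and mean ± SEM for
biological replicates.

Two-group comparisons use the unpaired two-tailed t test, pooled variance
by default with a Welch option; multi-group designs use one-way ANOVA
plus Dunnett's control-vs-each comparisons (scipy's multivariate-t
implementation; adjusted p ≥ the like-for-like unadjusted p at the same
pooled df). Significance is reported at α = 0.05. The empirical type-I
error at n = 3/group is verified to sit in [0.04, 0.06] over 10,000 null
simulations.

Assay arithmetic: glucose consumption = unconditioned − sample; lactate
production = sample − unconditioned (the sign that makes "production"
positive); ATP/ADP = background-subtracted ratio, flagged when the ADP
net is non-positive; relative expression = 2^−ΔΔCt against a reference
gene (the standard form, as the exact arithmetic is rarely stated);
everything "relative to untreated control" is a plain ratio.

Report bundles are directories of tidy CSVs plus a `manifest.json`
listing the package version, seed, input tables and every convention in
force (extremal conventions, PER constants, natural-abundance constants,
morphology cutoffs, statistical defaults); identical inputs and seed give
byte-identical bundles.

## Problem sizes and determinism

The test suite and acceptance script size their simulations to what the
checks need: 3 plates × 2 wells for scenario recovery, 25 randomized
traces for the formula oracle, 200 random MIDs for the round trip, 10⁶
molecules per grid point for solver-vs-oracle equivalence, 10⁴ null
replicates for test calibration, and a few hundred synthetic shapes for
classifier agreement. All randomness flows through numpy `Generator`
seeds (spawned via `SeedSequence` where several independent streams are
needed), so every reported number is reproducible bit for bit.
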