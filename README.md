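# metaboflux

Analysis toolkit for cellular-metabolism studies of the kind run on retinal
pigment epithelium (RPE) and other immune-competent cells: extracellular-flux
(Seahorse-style) stress tests, [U-¹³C]-glucose stable-isotope tracer analysis
(SITA), mitochondrial morphometry from electron-microscopy tracings, and the
replicate/statistics conventions that tie them together. Every analysis step
is paired with a seeded synthetic-data generator that produces instrument-like
inputs with known ground truth, so the whole pipeline is testable end to end
without access to an instrument or a mass spectrometer.

## What it computes

**Extracellular flux** (`metaboflux.flux`) — from per-well OCR/ECAR time
series plus an injection schedule:

- mitochondrial stress test (oligomycin → FCCP → rotenone/antimycin A):
  non-mitochondrial respiration (min OCR after rot/AA), basal respiration
  (last baseline OCR − non-mito), proton leak (min OCR after oligomycin −
  non-mito), ATP-linked respiration (basal − leak), maximal respiration
  (max OCR after FCCP − non-mito), spare respiratory capacity
  (100 × maximal/basal), and OCR/ECAR (first OCR / first ECAR);
- glycolysis stress test (glucose → oligomycin → 2-DG): non-glycolytic
  acidification, glycolysis, glycolytic capacity and reserve;
- glycolytic rate assay: PER = ECAR × buffer factor × chamber volume ×
  volume scaling, glycoPER = PER − ccf × OCR, basal and compensatory
  glycolysis, mitoOCR/glycoPER, %PER from glycolysis;
- UK5099/etomoxir injection differences (MPC-/CPT1-dependent respiration)
  and acute-injection fold changes between treated and control groups.

**Isotope tracing** (`metaboflux.sita`, `metaboflux.isotopes`) — raw
M+0…M+n intensities are deconvolved into natural-abundance-corrected
mass-isotopolog distributions (MIDs) via a binomial correction matrix and
nonnegative least squares; pools split into labeled (¹³C) and unlabeled
(¹²C) fractions per µg protein; and the pyruvate-entry surrogate ratios are
computed: citrate M+2 / pyruvate M+3 for pyruvate dehydrogenase (PDH) and
citrate M+3 / pyruvate M+3 for pyruvate carboxylase (PC). A steady-state
label-propagation simulator with a tunable PDH:PC split (validated against
a molecule-level Monte-Carlo oracle) provides ground-truth MIDs.

**Morphometry** (`metaboflux.morphometry`) — mean shoelace area over up to
three tracings, Feret diameter, a reproducible three-class morphology call
(fragmented / short tubular / long tubular) from the elongation statistic
e = diameter / (2·√(area/π)), and per-field counts and densities.

**Replicates & statistics** (`metaboflux.assay_stats`) — technical wells
average to one biological value per experiment before any test; unpaired
two-tailed t tests and one-way ANOVA with Dunnett's control-vs-each
comparisons; plate-assay arithmetic (glucose consumption, lactate
production, ATP/ADP ratio, 2^−ΔΔCt relative expression, fold changes).

## Worked example

Simulate an acute-LPS plate (ECAR rises 1.5-fold after injection in the
treated group) and recover the fold change:

```bash
$ metaboflux xf simulate --preset lps_acute --seed 7 --out plate.csv --config-out assay.yaml
wrote 8 traces to plate.csv
$ metaboflux xf analyze --plate plate.csv --config assay.yaml --test acute \
      --event lps --treated lps --control control --out acute.csv
wrote 1 parameter rows to acute.csv
$ cat acute.csv
well,group,parameter,value,unit,flag
,lps,acute_fold_change,1.5254018098975208,fold,
```

The value is the mean post-/pre-injection ECAR response of the treated
wells divided by that of the control wells (technical wells averaged
first): here 1.53×, i.e. the simulated 1.5-fold glycolytic switch
recovered to within the plate's 5% measurement noise. The same flow works
in Python:

```python
import metaboflux as mf

cfg = mf.preset("lps_acute", seed=7)
plates = [mf.segment_plate(p) for p in mf.simulate_experiments(cfg, 3, seed=7)]
res = mf.acute_injection_response(plates, "lps", "lps", "control", channel="ECAR")
print(res.fold_change)   # ~1.5 across 3 biological repeats
```

Isotope side, in three lines:

```python
mids = mf.simulate_mids(mf.LabelNetworkConfig(phi_pdh=0.6, phi_pc=0.15))
print(mf.pdh_surrogate(mids["citrate"], mids["pyruvate"]))  # 0.48...
print(mf.pc_surrogate(mids["citrate"], mids["pyruvate"]))   # 0.13...
```

## Layout

- `src/metaboflux/flux.py`, `flux_sim.py` — flux-trace analysis and plate simulator
- `src/metaboflux/sita.py`, `isotopes.py` — MID correction and label-network simulator
- `src/metaboflux/morphometry.py` — outline geometry, classification, shape generator
- `src/metaboflux/assay_stats.py`, `report.py` — replicate policy, statistics, report bundles
- `src/metaboflux/io.py`, `cli.py` — CSV/YAML dialects and the `metaboflux` CLI
- `docs/methods.md` — model assumptions, parameter defaults, numerical choices
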