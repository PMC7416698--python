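# foveapredict

Predicting foveal visual potential — foveal sensitivity (FS, dB) and decimal
visual acuity (VA) — from foveal photoreceptor structure on OCT, and turning
the predictions into per-patient *treatment potential* for blue cone
monochromacy (BCM)-like cohorts.

The pipeline, exercised end-to-end on synthetic data:

1. **`foveapredict.synth`** — synthetic cohorts (an IRD + normal training set
   whose FS/VA follow the log quantum-catch relation in foveal outer nuclear
   layer (ONL) thickness, plus BCM-like cohorts with non-detectable FS and
   short cone outer segments), and a B-scan renderer that draws Gaussian
   reflectance bands at ground-truth boundary depths with stored truth for
   oracle testing.
2. **`foveapredict.oct`** — B-scan processing: lateral downsampling, BrM
   alignment, foveola location, six-boundary segmentation
   (OPL/ELM/EZ/COST/RPE1/RPE2-BrM), thickness extraction, gradient-extrema
   counting, and the 7-eccentricity structural/reflectivity feature samples.
3. **`foveapredict.models`** — random-forest Models I (segmentation features +
   interaction terms) and II (raw reflectivity vectors) for FS and VA, with
   leave-one-subject-out cross-validation, RMSE, and ±1.96·RMSE prediction
   ranges.
4. **`foveapredict.curvefit`** — the quantum-catch curve `y = y0 + a·log10(ONL)`
   (least squares after the log transform) and the frozen clinical formulas
   (`va_from_onl`, `fs_from_onl`).
5. **`foveapredict.potential`** — treatment potential (prediction − measurement,
   with the non-detectable-FS → 0 dB floor), ETDRS line arithmetic, Snellen
   chart lines, and Kruskal–Wallis genotype/method comparisons (rank formula
   with tie correction + permutation oracle).
6. **`foveapredict.io` / `.config` / `.pipeline` / `.cli`** — TSV/CSV formats,
   YAML run configuration, and the end-to-end driver.

## CLI

```sh
foveapredict simulate cohort --group training --n 29 --seed 1 --out cohort.csv
foveapredict simulate scans --cohort cohort.csv --outdir scans/ --seed 1
foveapredict segment scans/S1_scan1.tsv --out seg.csv
foveapredict features scans/S1_scan1.tsv --out features.csv
foveapredict predict --onl 90 --va 0.2      # clinical formula worked example
foveapredict run-all --seed 1 --outdir results/run
```

`run-all` simulates the cohorts (26 IRD + 3 normals; 8 + 8 BCM), renders and
processes three scans per subject, runs 29-fold leave-one-subject-out
evaluation of the four forest models, fits the FS/VA log curves, predicts the
BCM cohorts by all three methods and writes potential reports, group
summaries and Kruskal–Wallis tests under `--outdir` (≈4 min on one CPU).
Every run persists its `config.yaml`; the same config + seed reproduces
byte-identical tables.

## Conventions

- Depth in μm, 0 at the RPE2/Bruch's-membrane band after alignment,
  increasing toward the vitreous; eccentricity in degrees, 0 at the foveola.
- Thicknesses: ONL = OPL − ELM, IS = ELM − EZ, COS = EZ − COST,
  RPE = RPE1 − RPE2/BrM. Flagged values are NaN, never silently zero.
- Non-detectable sensitivity is `None` in code and the literal `ND` in CSV.
- logMAR = −log10(decimal VA); 10 dB of sensitivity = 1 log unit.
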