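# tmaquant

Quantification of multiplexed immunofluorescence on tissue-microarray
(TMA) cores, from raw multi-channel images to patient survival
stratification.

TMA studies stain hundreds of small tissue cores ("spots") — typically
triplicate tumor cores per patient — with DAPI, pan-cytokeratin and
antibody panels against markers of interest (e.g. the inflammasome
proteins NLRC4, IL-18, IL-1β in colorectal cancer). The analytical
questions are always the same: where is the epithelium (tumor) versus the
stroma, how much marker does each cell express in each compartment, how do
measurements from consecutive serial sections line up, and do patients
stratified by marker level differ in overall survival. `tmaquant`
implements that chain as a tested, scriptable pipeline for image analysts
and biostatisticians, with a ground-truthed synthetic-data module so every
stage is verifiable without patient data.

## What it computes

- **Epithelial mask**: threshold on the cytokeratin channel + morphological
  opening/closing with physical-radius disks. Cells inside are epithelial,
  outside stromal.
- **Cells**: DAPI difference-of-Gaussians band-pass → threshold →
  watershed split; each nucleus gets a fixed-width (default 3 µm)
  cytosolic ring; compartments are nucleus, cytosol, and cell = union.
- **Per-cell features**: max / median / mean intensity of every channel
  over every compartment, written one row per cell to CSV.
- **Spot MFI**: for marker *m* and compartment class *c* ∈ {epithelial,
  stromal} with cells i = 1..n and per-cell median whole-cell intensities
  med_i(m),

      MFI(m, c) = (1/n) Σ_i med_i(m)

  — the mean of per-cell medians. Patient values average replicate cores.
- **Serial-section registration**: the rigid transform (rotation θ about
  the image center + translation t) maximizing normalized
  cross-correlation of DAPI channels, found by rotation grid search with
  per-angle phase correlation; used to transfer the cytokeratin mask onto
  a consecutive section stained with a different panel.
- **Stratification and survival**: marker cutoffs by ROC-Youden
  (argmax of sensitivity + specificity − 1 over midpoint thresholds) or by
  the sample median; Kaplan–Meier curves with median OS and the 5-year
  (60-month) rate, log-rank tests, single-covariate Cox
  proportional-hazards hazard ratios (Efron ties), and logistic regression
  of death on marker level.

See `docs/methods.md` for the full model, parameter defaults and
numerical conventions.

## Worked example

Run the whole pipeline on a self-generated study (12 synthetic patients,
3 cores each, planted hazard ratio 0.44 between marker-high and
marker-low strata):

```bash
tmaquant run --simulate --seed 2 --out demo
```

This writes `cells.csv`, `spots.csv`, `patients.csv`, `cutoffs.json`,
`survival.json`, the resolved config and a run log into `demo/`. With
seed 2 the survival summary reads (abridged):

```json
{
 "NLRC4": {
  "logrank_chi2": 1.59, "logrank_p": 0.207,
  "km": {
   "high": {"n": 7, "n_events": 5, "median_os": 152.4, "rate_at": {"60.0": 0.714}},
   "low":  {"n": 5, "n_events": 5, "median_os": 79.5,  "rate_at": {"60.0": 0.8}}
  },
  "cox": {"hazard_ratio": 0.436, "ci_low": 0.116, "ci_high": 1.642, "p": 0.220}
 }
}
```

Reading it: the imaging stages measured an epithelial NLRC4 MFI per
patient from the simulated cores; the ROC cutoff split the cohort 7 high /
5 low; marker-high patients die at 0.44× the rate of marker-low ones —
the pipeline recovers the planted hazard ratio — but at n = 12 the 95% CI
(0.12–1.64) spans 1 and the log-rank p of 0.21 is, correctly, not
significant. Effect recovery with tight intervals is demonstrated at
n = 2000–5000 in the test suite and the acceptance script.

Each stage is also its own subcommand (`tmaquant simulate core|pair|cohort`,
`segment`, `register`, `transfer-mask`, `quantify`, `run`), reading and
writing multi-page TIFF / OME-TIFF, CSV and JSON, with YAML configuration
(`--config`; unknown keys are rejected).

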