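# Methods

`tmaquant` quantifies multiplexed immunofluorescence on tissue-microarray
(TMA) cores and carries the measurements through to patient survival
stratification. This note records the models, the parameters that matter,
the numerical choices, and what the synthetic data can and cannot show.

## The measurement model

A core (one TMA spot) is a stack of co-registered 2-D fluorescence
channels: DAPI (nuclei), pan-cytokeratin (epithelium), and one or more
marker channels (e.g. NLRC4, IL-18, IL-1β), with a physical pixel size
(default 0.46 µm/px, a 20× slide-scanner class resolution).

**Epithelium.** The cytokeratin channel is thresholded (Otsu when
`threshold: auto`) and cleaned by morphological opening then closing with
disk structuring elements of physical radius (defaults 1 µm and 2 µm).
Opening removes speckle, closing fills holes smaller than its element; the
open-then-close filter is idempotent, so the detector is stable on its own
output. Cells inside the mask are "epithelial" (tumor, in tumor cores);
outside, "stromal".

**Cells.** Nuclei are detected on DAPI by a difference-of-Gaussians
band-pass with physical sigmas (defaults 1 µm / 8 µm — pass structures at
the nucleus scale, reject background), thresholded (Otsu on the filtered
image), 8-connected, and split by watershed seeded on local maxima of the
smoothed DAPI with a 4-µm minimum seed separation. Objects under
10 µm² are discarded and labels relabeled 1..N. A whole cell is its
nucleus plus a fixed-width cytosolic ring (default 3 µm, Euclidean
distance); ring pixels contested by several nuclei go to the nearest
nucleus footprint, ties to the lower label id — deterministic by
construction. Compartments therefore satisfy nucleus(k) ⊆ cell(k) =
nucleus(k) ∪ cytosol(k), with cells pairwise disjoint.

**Features and MFI.** For every cell, max/median/mean intensity of each
channel over each compartment. Epithelial membership is centroid-in-mask
(a majority-pixel rule is available via `quantification.membership`). The
spot readout for a marker and compartment class is the MFI: the arithmetic
mean over that class's cells of the per-cell median whole-cell intensity.
The per-cell median makes the readout robust to bright specks; the mean
over cells makes the spot value an unbiased average of cell levels.
Patient values average the MFIs of replicate cores (tumors are punched in
triplicate), skipping missing replicates; an unweighted mean by default,
cell-count weighting via config.

**Serial sections.** Consecutive 5-µm sections carry nearly identical
nuclear layouts, so sections stained with different panels are linked by a
rigid transform (rotation about the image center + translation) estimated
on DAPI: a coarse rotation grid (±20°, 1° step) with the translation
solved by phase correlation at each angle, then a 0.1° local refinement,
scored by normalized cross-correlation of background-subtracted DAPI. The
identity transform is always scored too, so registration never returns
something worse than not registering; a best score below `min_score`
(default 0.2) raises a low-confidence error carrying the score. Masks are
transferred with nearest-neighbor resampling and re-binarized, keeping
them strictly boolean.

## Stratification and survival

Patient marker values are dichotomized either at the sample median
("high" = value > median) or at the ROC-Youden cutoff against the death
indicator: candidate thresholds are the midpoints between consecutive
distinct values plus the ±∞ endpoints, the orientation is chosen so the
rank AUC is ≥ 0.5, and ties in Youden's J = sensitivity + specificity − 1
are broken toward the smallest threshold. The method is selected per
marker in config (ROC for NLRC4/IL-18, median for IL-1β by default,
mirroring the study this package models).

Strata feed Kaplan–Meier curves (median OS = first time S(t) ≤ 0.5,
"not reached" when the curve never crosses; 5-year rate = KM estimate at
60 months, not a crude fraction), the (k−1)-df log-rank test, a
single-covariate Cox proportional-hazards model (Efron tie handling,
via lifelines; HR = high vs low under the default reference coding), and
a logistic regression of death on the continuous marker (statsmodels;
odds ratio per unit, or per SD via option). Degenerate fits — perfect or
monotone separation, typically at very small n — are reported as errors in
`survival.json` per analysis rather than aborting the run: a
non-identifiable fit on a valid cohort is a result, not a failure.
No multiple-testing correction is applied across markers.

## The synthetic generator

Every stage is tested against ground-truthed synthetic data:

- **Cores** (default 320×320 px): nuclei are 2-D Gaussian bumps truncated
  at the nucleus radius (5–7 px), placed by dart throwing with a 34-px
  minimum center distance; the epithelial region is thresholded
  low-frequency Gaussian noise occupying a configurable area fraction
  (default 0.4), so its boundary is smooth but irregular; cytokeratin is a
  constant amplitude inside the region; each marker is painted *constant*
  over a generous cell footprint (nucleus radius + 10 px ≥ nucleus + ring)
  so the per-cell median is exactly the painted mean + background. The
  34-px spacing guarantees neighboring footprints never overlap. Noise is
  additive Gaussian on top of the noiseless render ("SNR 10" in the tests
  means sigma = DAPI amplitude / 10 = 20). Identical (config, seed) gives
  bitwise-identical output, and the noiseless image is exactly
  reconstructible from the truth record.
- **Serial pairs**: the second image is the first resampled under a known
  rigid transform plus independent noise; moves shedding > 50% of tissue
  are rejected.
- **Cohorts**: exponential event times with a two-level stratum hazard
  (baseline = "low"; high-stratum hazard = HR × baseline). Censoring is an
  independent exponential clock with rate λ·q/(1−q), which censors each
  record with probability exactly q while keeping KM/Cox estimates
  unbiased. Marker MFIs are normal around stratum means separated by a
  configurable effect. Defaults are the effect sizes of the colorectal
  cohort this package models: HR 0.44 (epithelial-marker high vs low),
  56.98-month low-stratum median OS, 104 patients, with a 35% five-year
  rate in the double-low stratum used for the rate-recovery check.

What the generator does **not** emulate: optics (point-spread convolution,
chromatic shifts, autofluorescence), staining gradients and batch effects,
tissue folds and tears, 3-D structure, cell-shape variety, and marker
spatial gradients within cells. Passing tests therefore demonstrate that
the algorithms are correct on images satisfying their stated assumptions,
not that the defaults are tuned for any particular scanner's output. The
scale and SNR defaults were chosen once for testability.

## Problem sizes and numerical choices

The test-suite simulations are sized for a single CPU: 20 seeded cores for
the detection-quality gates, 50 serial pairs for registration recovery,
200 replicates at n = 500 for Cox CI coverage, n = 2000–5000 cohorts for
effect-size recovery, and 100 replicates at the 104-patient cohort size
for the end-to-end power/size property (run with the median-cutoff
configuration; the ROC cutoff, being optimized against the outcome,
produces less stable thresholds at that sample size). Monte-Carlo
tolerances follow the estimator variances (e.g. the KM median at n = 2000
has sd ≈ 1.9 months).

Numerical conventions worth knowing: 0-based (row, col) pixel coordinates,
origin top-left; rotations act about the image center, so composing two
transforms has a closed form and `compose(T, invert(T))` is exact to
1e−9; image resampling uses linear interpolation for intensities and
nearest-neighbor for masks/labels (value-set preserving), out-of-frame
pixels 0; positivity thresholds are inclusive (≥); a cytosol whose ring is
fully contested carries missing statistics and makes any rule referencing
it negative-and-flagged; missing values are empty CSV fields, never
sentinels; CSV floats are written with `%.17g` and parsed in round-trip
mode so tables survive a write/read cycle bit-exactly; config files reject
unknown keys and every run writes its resolved config next to the outputs.

## Known limitations

- Rigid-only registration: a badly folded or stretched section will
  surface as a low-confidence error, not be corrected.
- The watershed is seeded on smoothed-DAPI maxima; heavily overlapping
  nuclei (> ~30% footprint overlap) may merge.
- The ROC-Youden cutoff is estimated on the same cohort it stratifies;
  like any optimal-cutpoint method it is anticonservative, which is why
  the power/size property is stated for the median configuration.
- Patient aggregation assumes replicate cores are exchangeable; no
  within-patient heterogeneity model.
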