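"""Ground-truthed synthetic TMA cores, serial-section pairs, and cohorts.

The generator emulates what the downstream stages must cope with on real
multiplexed-immunofluorescence spots:

* a disk-shaped tissue core holding an irregular epithelial region
  (thresholded low-frequency noise, so its boundary is smooth but not
  geometric),
* DAPI nuclei rendered as 2-D Gaussian blobs truncated at the nucleus
  radius (point-spread-like, watershed-friendly), placed with a minimum
  center separation,
* a pan-cytokeratin channel that is high inside the epithelial region and
  at background outside,
* marker channels painted *constant* over each cell footprint (nucleus plus
  cytosolic ring plus a safety margin) before noise, so the per-cell median
  is an exactly known quantity,
* additive Gaussian read-out noise on top of a flat background.

Clinical cohorts are simulated with exponential event times whose hazard
depends on a two-level stratum, independent exponential censoring tuned to
a target censoring fraction, and per-patient marker MFIs separated between
strata so the planted grouping is recoverable by thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import math

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import Core
from .errors import ConfigurationError, GenerationError
from .transforms import RigidTransform2D


# --------------------------------------------------------------------------
# core images
# --------------------------------------------------------------------------

@dataclass
class CoreSimConfig:
    """Parameters of one synthetic core image.

    Intensities are arbitrary fluorescence units; lengths are pixels unless
    suffixed ``_um``. Defaults give a 320x320 px field at 0.46 um/px
    (NanoZoomer 20x class) with 50 nuclei.
    """

    shape: tuple[int, int] = (320, 320)
    pixel_size_um: float = 0.46
    channels: tuple[str, ...] = ("DAPI", "cytokeratin", "NLRC4")
    n_nuclei: int = 50
    nucleus_radius_px: tuple[float, float] = (5.0, 7.0)
    # 2*(max radius + margin): marker footprints of neighboring cells never overlap
    min_center_distance_px: float = 34.0
    ring_margin_px: float = 10.0  # marker paint radius = nucleus radius + margin
    epithelial_area_fraction: float = 0.4
    epithelium_smooth_sigma_px: float = 25.0
    background_level: float = 10.0
    dapi_amplitude: float = 200.0
    cytokeratin_amplitude: float = 100.0
    marker_mean_epithelial: float = 120.0
    marker_mean_stromal: float = 40.0
    marker_cell_sd: float = 10.0  # cell-to-cell spread of the painted mean
    noise_sigma: float = 0.0
    max_placement_tries: int = 50000

    def validate(self) -> None:
        if "DAPI" not in self.channels or "cytokeratin" not in self.channels:
            raise ConfigurationError("channel list must include 'DAPI' and 'cytokeratin'")
        if self.nucleus_radius_px[0] > self.nucleus_radius_px[1]:
            raise ConfigurationError("nucleus radius range must be (low, high)")
        if self.noise_sigma < 0 or self.background_level < 0:
            raise ConfigurationError("noise sigma and background must be non-negative")

    @property
    def marker_channels(self) -> tuple[str, ...]:
        return tuple(c for c in self.channels if c not in ("DAPI", "cytokeratin"))


@dataclass
class SyntheticCoreTruth:
    """Everything needed to reconstruct the noiseless core exactly."""

    nucleus_centers: np.ndarray        # (N, 2) float (row, col)
    nucleus_radii: np.ndarray          # (N,) float px
    epithelial_region: np.ndarray      # bool, image shape
    per_cell_marker_means: dict[int, dict[str, float]]  # cell index -> channel -> mean
    in_epithelium: np.ndarray          # (N,) bool, center inside region
    noise_sigma: float
    background_level: float
    config: CoreSimConfig


def _sample_centers(rng: np.random.Generator, cfg: CoreSimConfig) -> np.ndarray:
    """Dart-throwing with a minimum pairwise distance; bounded retries."""
    h, w = cfg.shape
    pad = cfg.nucleus_radius_px[1] + 2.0
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < cfg.n_nuclei:
        if tries >= cfg.max_placement_tries:
            raise GenerationError(
                f"could not place {cfg.n_nuclei} nuclei at min distance "
                f"{cfg.min_center_distance_px} px in a {h}x{w} image "
                f"({len(centers)} placed after {tries} tries)"
            )
        tries += 1
        cand = np.array([rng.uniform(pad, h - 1 - pad), rng.uniform(pad, w - 1 - pad)])
        if all(np.hypot(*(cand - c)) >= cfg.min_center_distance_px for c in centers):
            centers.append(cand)
    return np.array(centers).reshape(len(centers), 2)


def _epithelial_region(rng: np.random.Generator, cfg: CoreSimConfig) -> np.ndarray:
    """Smoothed white noise thresholded at a quantile -> irregular blob mask."""
    noise = rng.standard_normal(cfg.shape)
    smooth = ndimage.gaussian_filter(noise, cfg.epithelium_smooth_sigma_px)
    thr = np.quantile(smooth, 1.0 - cfg.epithelial_area_fraction)
    return smooth > thr


def _gaussian_blob(shape, center, radius, amplitude) -> np.ndarray:
    """Gaussian bump truncated at ``radius`` (zero outside the footprint)."""
    r0, c0 = center
    lo_r = max(int(math.floor(r0 - radius)), 0)
    hi_r = min(int(math.ceil(r0 + radius)) + 1, shape[0])
    lo_c = max(int(math.floor(c0 - radius)), 0)
    hi_c = min(int(math.ceil(c0 + radius)) + 1, shape[1])
    rr, cc = np.mgrid[lo_r:hi_r, lo_c:hi_c]
    d2 = (rr - r0) ** 2 + (cc - c0) ** 2
    sigma = radius / 2.0
    patch = amplitude * np.exp(-d2 / (2 * sigma**2))
    patch[d2 > radius**2] = 0.0
    out = np.zeros(shape)
    out[lo_r:hi_r, lo_c:hi_c] = patch
    return out


def _disk_mask(shape, center, radius) -> np.ndarray:
    r0, c0 = center
    lo_r = max(int(math.floor(r0 - radius)), 0)
    hi_r = min(int(math.ceil(r0 + radius)) + 1, shape[0])
    lo_c = max(int(math.floor(c0 - radius)), 0)
    hi_c = min(int(math.ceil(c0 + radius)) + 1, shape[1])
    rr, cc = np.mgrid[lo_r:hi_r, lo_c:hi_c]
    out = np.zeros(shape, dtype=bool)
    out[lo_r:hi_r, lo_c:hi_c] = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    return out


def render_noiseless(truth: SyntheticCoreTruth) -> dict[str, np.ndarray]:
    """Deterministically reconstruct every channel of the core without noise.

    This is the pixelwise ground truth: ``simulate_core`` with
    ``noise_sigma=0`` returns exactly these arrays.
    """
    cfg = truth.config
    shape = cfg.shape
    out: dict[str, np.ndarray] = {}
    dapi = np.full(shape, truth.background_level, dtype=float)
    for center, radius in zip(truth.nucleus_centers, truth.nucleus_radii):
        dapi += _gaussian_blob(shape, center, radius, cfg.dapi_amplitude)
    out["DAPI"] = dapi

    ck = np.full(shape, truth.background_level, dtype=float)
    ck[truth.epithelial_region] += cfg.cytokeratin_amplitude
    out["cytokeratin"] = ck

    for ch in cfg.marker_channels:
        img = np.full(shape, truth.background_level, dtype=float)
        for k, (center, radius) in enumerate(zip(truth.nucleus_centers, truth.nucleus_radii)):
            foot = _disk_mask(shape, center, radius + cfg.ring_margin_px)
            img[foot] = truth.background_level + truth.per_cell_marker_means[k][ch]
        out[ch] = img
    return out


def simulate_core(config: CoreSimConfig, seed: int) -> tuple[Core, SyntheticCoreTruth]:
    """Generate one synthetic core image plus its ground truth.

    The same ``(config, seed)`` pair always produces bitwise-identical
    output. Marker means are drawn per cell around the epithelial or stromal
    class mean depending on whether the nucleus center falls inside the
    ground-truth epithelial region, truncated at zero.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    region = _epithelial_region(rng, config)
    centers = _sample_centers(rng, config)
    radii = rng.uniform(*config.nucleus_radius_px, size=len(centers))
    if len(centers):
        idx = np.round(centers).astype(int)
        in_epi = region[idx[:, 0], idx[:, 1]]
    else:
        in_epi = np.zeros(0, dtype=bool)

    means: dict[int, dict[str, float]] = {}
    for k in range(len(centers)):
        means[k] = {}
        for ch in config.marker_channels:
            mu = config.marker_mean_epithelial if in_epi[k] else config.marker_mean_stromal
            means[k][ch] = float(max(0.0, rng.normal(mu, config.marker_cell_sd)))

    truth = SyntheticCoreTruth(
        nucleus_centers=centers,
        nucleus_radii=radii,
        epithelial_region=region,
        per_cell_marker_means=means,
        in_epithelium=in_epi,
        noise_sigma=config.noise_sigma,
        background_level=config.background_level,
        config=config,
    )
    channels = render_noiseless(truth)
    if config.noise_sigma > 0:
        for name in config.channels:
            noisy = channels[name] + rng.normal(0.0, config.noise_sigma, size=config.shape)
            channels[name] = np.clip(noisy, 0.0, None)
    # preserve the configured channel order
    ordered = {name: channels[name] for name in config.channels}
    core = Core(channels=ordered, pixel_size_um=config.pixel_size_um, core_id=f"sim-{seed}")
    return core, truth


# --------------------------------------------------------------------------
# serial-section pairs
# --------------------------------------------------------------------------

def simulate_serial_pair(
    core: Core,
    transform: RigidTransform2D,
    seed: int,
    noise_sigma: float = 0.0,
) -> tuple[Core, Core]:
    """Derive a consecutive-slide image from ``core`` by a known rigid move.

    The second image is the first resampled under ``transform`` (linear
    interpolation, zeros outside the frame) plus independent Gaussian noise.
    Raises ``GenerationError`` if the move pushes more than half of the
    tissue (above-background DAPI) out of frame, and ``ConfigurationError``
    for rotations beyond +/-30 degrees.
    """
    from .registration import apply_transform  # local import avoids a cycle

    if abs(transform.rotation_deg) > 30.0:
        raise ConfigurationError("serial-section rotations beyond 30 degrees are not simulated")
    rng = np.random.default_rng(seed)
    dapi = core.channel("DAPI")
    tissue = dapi > (np.median(dapi) + 1e-9)
    moved_tissue = apply_transform(tissue.astype(float), transform, interpolation="nearest") > 0.5
    n0 = max(int(tissue.sum()), 1)
    if moved_tissue.sum() < 0.5 * n0:
        raise GenerationError(
            f"transform moves {1 - moved_tissue.sum() / n0:.0%} of tissue out of frame (> 50%)"
        )
    channels = {}
    for name, img in core.channels.items():
        warped = apply_transform(img, transform, interpolation="linear")
        if noise_sigma > 0:
            warped = np.clip(warped + rng.normal(0.0, noise_sigma, size=img.shape), 0.0, None)
        channels[name] = warped
    second = Core(channels=channels, pixel_size_um=core.pixel_size_um,
                  core_id=f"{core.core_id}-serial")
    return core, second


# --------------------------------------------------------------------------
# clinical cohorts
# --------------------------------------------------------------------------

@dataclass
class SyntheticCohortTruth:
    """Generating parameters of a two-stratum survival cohort.

    The baseline stratum is ``"low"`` (marker-low); the ``"high"`` stratum's
    event hazard is ``generating_hazard_ratio`` times the baseline hazard,
    so a ratio below 1 means marker-high patients do better. Defaults are
    the effect sizes of the colorectal-cancer cohort this package models:
    high-vs-low hazard ratio 0.44 and a 56.98-month median overall survival
    in the low stratum.
    """

    generating_hazard_ratio: float = 0.44
    baseline_median_survival: float = 56.98   # months, "low" stratum
    marker_effect: float = 40.0               # high-vs-low difference in epithelial MFI
    marker_low_mean: float = 60.0
    marker_patient_sd: float = 8.0
    censoring_rate: float = 0.2
    high_fraction: float = 0.5
    marker_name: str = "NLRC4"

    def validate(self) -> None:
        if self.generating_hazard_ratio <= 0:
            raise ConfigurationError("generating_hazard_ratio must be > 0")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ConfigurationError("censoring_rate must be in [0, 1)")


def simulate_cohort(
    n_patients: int, truth: SyntheticCohortTruth, seed: int
) -> pd.DataFrame:
    """Simulate a clinical table with per-patient marker MFIs.

    Event times are exponential with stratum-dependent hazard; censoring is
    by an independent exponential clock whose rate is tuned per stratum so
    each record is censored with probability ``censoring_rate`` (for
    exponential T and C, P(C < T) = lam_c / (lam_c + lam_t)). Observed time
    is min(T, C); ``event`` is 1 when the death is observed. Marker MFIs are
    normal around stratum means separated by ``marker_effect``. Tumor stage
    is drawn with the cohort's observed proportions and is independent of
    the planted stratum.
    """
    truth.validate()
    if n_patients < 2:
        raise ConfigurationError("need at least 2 patients")
    rng = np.random.default_rng(seed)
    group = np.where(rng.random(n_patients) < truth.high_fraction, "high", "low")
    lam_low = math.log(2.0) / truth.baseline_median_survival
    lam = np.where(group == "high", lam_low * truth.generating_hazard_ratio, lam_low)
    t_event = rng.exponential(1.0 / lam)
    if truth.censoring_rate > 0:
        q = truth.censoring_rate
        lam_c = lam * q / (1.0 - q)
        t_cens = rng.exponential(1.0 / lam_c)
    else:
        t_cens = np.full(n_patients, np.inf)
    os_months = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    mfi = rng.normal(
        np.where(group == "high", truth.marker_low_mean + truth.marker_effect,
                 truth.marker_low_mean),
        truth.marker_patient_sd,
    )
    mfi = np.clip(mfi, 0.0, None)
    stage = rng.choice(["I-II", "III", "IV"], size=n_patients, p=[0.42, 0.36, 0.22])
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n_patients)],
            "group": group,
            "stage": stage,
            "os_months": os_months,
            "event": event,
            f"{truth.marker_name}_epithelial": mfi,
        }
    )


# --------------------------------------------------------------------------
# full simulated study (images + cohort), used by `run --simulate`
# --------------------------------------------------------------------------

@dataclass
class StudySimConfig:
    """A small end-to-end study: a cohort plus replicate core images.

    Each patient contributes ``cores_per_patient`` tumor cores whose
    epithelial marker means center on the patient's generating MFI, so the
    imaging pipeline should recover the cohort table's marker values.
    """

    n_patients: int = 12
    cores_per_patient: int = 3
    cohort: SyntheticCohortTruth = field(default_factory=SyntheticCohortTruth)
    core: CoreSimConfig = field(default_factory=CoreSimConfig)


def simulate_study(
    config: StudySimConfig, seed: int
) -> tuple[list[tuple[Core, SyntheticCoreTruth]], pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate cohort + images.

    Returns ``(cores_with_truths, core_map, clinical, cohort_truth)`` where
    ``clinical`` carries only what a real study would provide (patient id,
    stage, follow-up) and ``cohort_truth`` keeps the generating per-patient
    marker means and stratum for validation.
    """
    rng = np.random.default_rng(seed)
    clinical = simulate_cohort(config.n_patients, config.cohort, seed=int(rng.integers(2**31)))
    marker = config.cohort.marker_name
    cores: list[tuple[Core, SyntheticCoreTruth]] = []
    rows = []
    for _, patient in clinical.iterrows():
        for j in range(config.cores_per_patient):
            core_cfg = replace(
                config.core,
                channels=("DAPI", "cytokeratin", marker),
                marker_mean_epithelial=float(patient[f"{marker}_epithelial"]),
            )
            core, truth = simulate_core(core_cfg, seed=int(rng.integers(2**31)))
            core.core_id = f"{patient.patient_id}-c{j}"
            cores.append((core, truth))
            rows.append({"core_id": core.core_id, "patient_id": patient.patient_id})
    core_map = pd.DataFrame(rows)
    truth_tbl = clinical[["patient_id", "group", f"{marker}_epithelial"]].rename(
        columns={f"{marker}_epithelial": f"true_{marker}_epithelial"}
    )
    return cores, core_map, clinical.drop(columns=[f"{marker}_epithelial"]), truth_tbl
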