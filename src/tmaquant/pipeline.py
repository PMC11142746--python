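"""End-to-end orchestration: segment -> (transfer) -> quantify -> aggregate
-> stratify -> survive.

``run_pipeline`` consumes a directory of core TIFFs plus a core→patient map
and a clinical table (or simulates them under a seed), runs every stage,
and writes cells.csv, spots.csv, patients.csv, cutoffs.json, survival.json
and a run log into the output directory. Any stage failure aborts with the
stage name and the offending input id.
"""

from __future__ import annotations

import logging
from pathlib import Path
import sys

import pandas as pd

from . import io as tio
from .config import PipelineConfig
from .containers import Core
from .errors import (
    AnalysisError,
    DegenerateInputError,
    FitConvergenceError,
    InputDataError,
    TmaQuantError,
)
from .quantification import (
    aggregate_patients,
    measure_cells,
    records_to_dataframe,
    summarize_spot,
)
from .registration import RegistrationConfig, estimate_rigid, transfer_mask
from .segmentation import build_cell_compartments, detect_epithelium, detect_nuclei
from .survival import cox_fit, km_logrank, logistic_death_association, median_cutoff, roc_cutoff, stratify
from .synthetic import (
    CoreSimConfig,
    StudySimConfig,
    SyntheticCohortTruth,
    simulate_study,
)

log = logging.getLogger("tmaquant")


def _setup_logging(out_dir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr), logging.FileHandler(out_dir / "run.log")):
        handler.setFormatter(fmt)
        log.addHandler(handler)


class StageError(TmaQuantError):
    def __init__(self, stage: str, input_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {input_id!r}: {cause}")
        self.stage = stage
        self.input_id = input_id


def _simulate_inputs(config: PipelineConfig, input_dir: Path) -> None:
    """Write a fully synthetic study (cores + tables) into ``input_dir``."""
    sim = config.simulate
    marker = config.channels.markers[0]
    study = StudySimConfig(
        n_patients=sim.n_patients,
        cores_per_patient=sim.cores_per_patient,
        cohort=SyntheticCohortTruth(
            generating_hazard_ratio=sim.hazard_ratio,
            baseline_median_survival=sim.baseline_median_survival,
            marker_effect=sim.marker_effect,
            censoring_rate=sim.censoring_rate,
            marker_name=marker,
        ),
        core=CoreSimConfig(
            shape=(sim.image_size, sim.image_size),
            n_nuclei=sim.n_nuclei,
            noise_sigma=sim.noise_sigma,
            pixel_size_um=config.pixel_size_um,
            channels=("DAPI", "cytokeratin", marker),
        ),
    )
    cores, core_map, clinical, truth = simulate_study(study, seed=config.seed)
    input_dir.mkdir(parents=True, exist_ok=True)
    for core, _ in cores:
        tio.write_core(core, input_dir / f"{core.core_id}.tif")
    tio.write_table(core_map, input_dir / "core_map.csv")
    tio.write_table(clinical, input_dir / "clinical.csv")
    tio.write_table(truth, input_dir / "cohort_truth.csv")
    log.info("simulated %d cores for %d patients", len(cores), sim.n_patients)


def _load_cores(config: PipelineConfig, input_dir: Path) -> list[Core]:
    paths = sorted(input_dir.glob("*.tif")) + sorted(input_dir.glob("*.tiff"))
    if not paths:
        raise InputDataError(f"no core TIFFs found in {input_dir}")
    cores = []
    for p in paths:
        try:
            cores.append(tio.read_core(p))
        except InputDataError:
            # metadata lacked a pixel size; fall back to the configured one
            cores.append(tio.read_core(p, pixel_size_um=config.pixel_size_um))
    return cores


def quantify_core(core: Core, config: PipelineConfig, epithelium=None) -> pd.DataFrame:
    """Segment one core (unless a transferred mask is supplied) and measure it."""
    seg = config.segmentation
    if epithelium is None:
        epithelium = detect_epithelium(
            core,
            channel=config.channels.cytokeratin,
            threshold=seg.threshold,
            closing_radius_um=seg.closing_radius_um,
            opening_radius_um=seg.opening_radius_um,
        )
    nuclei = detect_nuclei(
        core,
        bandpass_sigmas_um=seg.bandpass_sigmas_um,
        background_offset=seg.background_offset,
        min_nucleus_area_um2=seg.min_nucleus_area_um2,
        seed_min_distance_um=seg.seed_min_distance_um,
    )
    cells, cytosols = build_cell_compartments(nuclei, seg.ring_width_um, core.pixel_size_um)
    records = measure_cells(core, nuclei, cells, cytosols, epithelium,
                            membership=config.quantification.membership)
    return records, summarize_spot(records, markers=config.channels.markers)


def run_pipeline(config: PipelineConfig, input_dir=None, simulate: bool = False) -> Path:
    """Execute all stages; returns the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    config.to_yaml(out / "resolved_config.yaml")
    log.info("tmaquant run, seed=%d", config.seed)

    if simulate:
        input_dir = out / "inputs"
        _simulate_inputs(config, input_dir)
    input_dir = Path(input_dir)

    core_map = tio.read_table(input_dir / "core_map.csv", required=["core_id", "patient_id"])
    clinical = tio.read_table(
        input_dir / "clinical.csv", required=["patient_id", "os_months", "event"]
    )

    cores = _load_cores(config, input_dir)
    # optional serial-section registration: pairs.csv lists (fixed, moving)
    transferred = {}
    pairs_path = input_dir / "pairs.csv"
    if config.registration.enabled and pairs_path.exists():
        by_id = {c.core_id: c for c in cores}
        pairs = tio.read_table(pairs_path, required=["fixed_core", "moving_core"])
        reg_cfg = RegistrationConfig(
            rotation_range_deg=config.registration.rotation_range_deg,
            coarse_step_deg=config.registration.coarse_step_deg,
            fine_step_deg=config.registration.fine_step_deg,
            min_score=config.registration.min_score,
        )
        for _, row in pairs.iterrows():
            fixed, moving = by_id[row.fixed_core], by_id[row.moving_core]
            try:
                t, score = estimate_rigid(fixed, moving, reg_cfg)
                seg = config.segmentation
                mask = detect_epithelium(
                    moving, channel=config.channels.cytokeratin, threshold=seg.threshold,
                    closing_radius_um=seg.closing_radius_um,
                    opening_radius_um=seg.opening_radius_um,
                )
                transferred[fixed.core_id] = transfer_mask(mask, t)
                t.to_json(out / f"transform_{row.moving_core}_to_{row.fixed_core}.json")
                log.info("registered %s -> %s (score %.3f)", row.moving_core,
                         row.fixed_core, score)
            except TmaQuantError as exc:
                raise StageError("register", str(row.moving_core), exc) from exc

    cell_frames, spot_frames = [], []
    for core in cores:
        try:
            records, spots = quantify_core(core, config,
                                           epithelium=transferred.get(core.core_id))
            cell_frames.append(records_to_dataframe(records))
            spot_frames.append(spots)
            log.info("core %s: %d cells", core.core_id, len(records))
        except TmaQuantError as exc:
            raise StageError("quantify", core.core_id, exc) from exc

    cells_df = pd.concat([f for f in cell_frames if not f.empty], ignore_index=True)
    spots_df = pd.concat(spot_frames, ignore_index=True)
    tio.write_table(cells_df, out / "cells.csv")
    tio.write_table(spots_df, out / "spots.csv")

    try:
        patients = aggregate_patients(spots_df, core_map, clinical,
                                      weighting=config.quantification.weighting)
    except TmaQuantError as exc:
        raise StageError("aggregate", "patients", exc) from exc

    strat = config.stratification
    cutoffs = []
    for marker in config.channels.markers:
        col = f"{marker}_{strat.compartment_class}"
        sub = patients.dropna(subset=[col])
        try:
            cut = None
            if config.cutoff_method(marker) == "roc":
                try:
                    cut = roc_cutoff(sub[col].to_numpy(), sub["event"].to_numpy(),
                                     marker=marker, compartment_class=strat.compartment_class)
                except DegenerateInputError as exc:
                    # an unusable ROC (one-class outcome, flat values) falls
                    # back to the median cutoff, as when a marker's ROC lacks
                    # adequate sensitivity/specificity
                    log.warning("ROC cutoff for %s unusable (%s); using median", marker, exc)
                if cut is not None and cut.degenerate:
                    log.warning("ROC cutoff for %s degenerate; using median", marker)
                    cut = None
            if cut is None:
                cut = median_cutoff(sub[col].to_numpy(), marker=marker,
                                    compartment_class=strat.compartment_class)
        except TmaQuantError as exc:
            raise StageError("stratify", marker, exc) from exc
        cutoffs.append(cut)
    patients = stratify(patients, cutoffs, combine=strat.combine)
    tio.write_table(patients, out / "patients.csv")
    tio.write_json([c.to_dict() for c in cutoffs], out / "cutoffs.json")

    results = {}
    for marker in config.channels.markers:
        col = f"{marker}_{strat.compartment_class}"
        entry = {}
        try:
            fit = km_logrank(patients, f"stratum_{col}", horizons=strat.horizons)
            entry["logrank_chi2"] = fit.logrank_chi2
            entry["logrank_p"] = fit.logrank_p
            entry["km"] = {
                label: {
                    "n": s.n,
                    "n_events": s.n_events,
                    "median_os": s.median_os if s.median_os is not None else "not reached",
                    "rate_at": {str(h): v for h, v in s.rate_at.items()},
                }
                for label, s in fit.strata.items()
            }
        except AnalysisError as exc:
            raise StageError("survive", marker, exc) from exc
        # degenerate fits (e.g. perfect separation at tiny n) are a result,
        # not a pipeline failure: record them per analysis
        for name, fit_call in (
            ("cox", lambda: cox_fit(patients, f"stratum_{col}")),
            ("logistic", lambda: logistic_death_association(patients, col)),
        ):
            try:
                entry[name] = fit_call()
            except (FitConvergenceError, DegenerateInputError) as exc:
                entry[name] = {"error": str(exc)}
        results[marker] = entry
    tio.write_json(results, out / "survival.json")
    log.info("pipeline complete: %s", out)
    return out
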