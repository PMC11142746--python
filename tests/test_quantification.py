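"""Per-cell statistics, positivity, spot MFI, and patient aggregation."""

import math

import numpy as np
import pandas as pd
import pytest

from tmaquant.containers import Core, EpithelialMask, LabelMap
from tmaquant.errors import ConfigurationError, InputDataError
from tmaquant.quantification import (
    PositivityRule,
    aggregate_patients,
    call_positivity,
    measure_cells,
    records_from_dataframe,
    records_to_dataframe,
    summarize_spot,
)
from tmaquant.segmentation import build_cell_compartments, detect_epithelium, detect_nuclei
from tmaquant.synthetic import StudySimConfig, CoreSimConfig, simulate_study


def tiny_core_setup(values, nucleus_rows=(3, 4, 5)):
    """A 9x9 core with a single 3x3 nucleus whose marker pixels are given."""
    img = np.zeros((9, 9))
    lab = np.zeros((9, 9), dtype=np.int32)
    vals = np.asarray(values, dtype=float).ravel()
    k = 0
    for r in nucleus_rows:
        for c in (3, 4, 5):
            lab[r, c] = 1
            img[r, c] = vals[k % len(vals)]
            k += 1
    core = Core({"DAPI": np.zeros((9, 9)), "marker": img}, pixel_size_um=1.0)
    nuclei = LabelMap(lab, "nucleus")
    cells, cyt = build_cell_compartments(nuclei, ring_width_um=1.0, pixel_size_um=1.0)
    mask = EpithelialMask(np.ones((9, 9), dtype=bool))
    return core, nuclei, cells, cyt, mask


class TestMeasureCells:
    def test_uniform_cell_gives_equal_stats_everywhere(self):
        core, nuclei, cells, cyt, mask = tiny_core_setup([7.0])
        core.channels["marker"][:] = 7.0
        recs = measure_cells(core, nuclei, cells, cyt, mask)
        assert len(recs) == 1
        for comp in ("cell", "nucleus", "cytosol"):
            for stat in ("max", "median", "mean"):
                assert recs[0].feature("marker", comp, stat) == 7.0

    def test_three_pixel_cell_median_mean_max(self):
        # direct arithmetic oracle on {1, 2, 100}
        img = np.zeros((7, 7))
        lab = np.zeros((7, 7), dtype=np.int32)
        for c, v in zip((2, 3, 4), (1.0, 2.0, 100.0)):
            lab[3, c] = 1
            img[3, c] = v
        core = Core({"marker": img}, pixel_size_um=1.0)
        nuclei = LabelMap(lab, "nucleus")
        cyt = LabelMap(np.zeros_like(lab), "cytosol")
        cells = LabelMap(lab.copy(), "cell")
        mask = EpithelialMask(np.zeros((7, 7), dtype=bool))
        rec = measure_cells(core, nuclei, cells, cyt, mask)[0]
        assert rec.feature("marker", "nucleus", "median") == 2.0
        assert abs(rec.feature("marker", "nucleus", "mean") - 103.0 / 3) < 1e-12
        assert rec.feature("marker", "nucleus", "max") == 100.0
        assert math.isnan(rec.feature("marker", "cytosol", "median"))
        assert not rec.in_epithelium

    def test_noiseless_synthetic_medians_equal_generating_means(self, segmented_noiseless):
        s = segmented_noiseless
        recs = measure_cells(s["core"], s["nuclei"], s["cells"], s["cytosols"], s["mask"])
        truth = s["truth"]
        labels = s["nuclei"].labels
        by_id = {r.cell_id: r for r in recs}
        for k, (r, c) in enumerate(np.round(truth.nucleus_centers).astype(int)):
            rec = by_id[labels[r, c]]
            expected = truth.per_cell_marker_means[k]["NLRC4"] + truth.background_level
            for comp in ("cell", "nucleus", "cytosol"):
                assert rec.feature("NLRC4", comp, "median") == expected
                assert rec.feature("NLRC4", comp, "max") == expected
            assert rec.in_epithelium == truth.in_epithelium[k]

    def test_majority_membership_option(self):
        core, nuclei, cells, cyt, _ = tiny_core_setup([1.0])
        half = np.zeros((9, 9), dtype=bool)
        half[:, :4] = True  # centroid col 4 is outside; most cell pixels too
        mask = EpithelialMask(half)
        rec_c = measure_cells(core, nuclei, cells, cyt, mask, membership="centroid")[0]
        rec_m = measure_cells(core, nuclei, cells, cyt, mask, membership="majority")[0]
        assert not rec_c.in_epithelium and not rec_m.in_epithelium
        with pytest.raises(ConfigurationError):
            measure_cells(core, nuclei, cells, cyt, mask, membership="most")


class TestCallPositivity:
    def make_records(self):
        core, nuclei, cells, cyt, mask = tiny_core_setup([10.0])
        return measure_cells(core, nuclei, cells, cyt, mask)

    def test_threshold_is_inclusive_at_boundary(self):
        recs = self.make_records()  # cell median exactly 10 inside nucleus
        rule = PositivityRule("m", [("marker__nucleus__median", "ge", 10.0)])
        assert call_positivity(recs, [rule])[0].positivity["m"] is True
        rule_hi = PositivityRule("m2", [("marker__nucleus__median", "ge", 10.0001)])
        assert call_positivity(recs, [rule_hi])[0].positivity["m2"] is False

    def test_conjunction_with_epithelium_matches_bruteforce(self, segmented_noiseless):
        s = segmented_noiseless
        recs = measure_cells(s["core"], s["nuclei"], s["cells"], s["cytosols"], s["mask"])
        thr = 110.0
        rule = PositivityRule("NLRC4", [("NLRC4__cell__median", "ge", thr)],
                              require_epithelium=True)
        call_positivity(recs, [rule])
        for r in recs:
            expected = (r.feature("NLRC4", "cell", "median") >= thr) and r.in_epithelium
            assert r.positivity["NLRC4"] == expected
        assert any(r.positivity["NLRC4"] for r in recs)
        assert any(not r.positivity["NLRC4"] for r in recs)

    def test_missing_feature_negative_and_flagged(self):
        recs = self.make_records()
        recs[0].features[("marker", "cytosol", "median")] = math.nan
        rule = PositivityRule("m", [("marker__cytosol__median", "ge", 1.0)])
        call_positivity(recs, [rule])
        assert recs[0].positivity["m"] is False
        assert recs[0].positivity_flagged["m"] is True

    def test_unknown_feature_is_configuration_error(self):
        recs = self.make_records()
        with pytest.raises(ConfigurationError):
            call_positivity(recs, [PositivityRule("m", [("nope__cell__median", "ge", 1.0)])])

    def test_empty_record_list_passes_through(self):
        assert call_positivity([], [PositivityRule("m", [("a__cell__median", "ge", 1)])]) == []


class TestSummarizeSpot:
    def _record(self, core_id, cell_id, median, in_epi):
        from tmaquant.quantification import CellFeatureRecord

        return CellFeatureRecord(
            core_id=core_id, cell_id=cell_id, centroid=(0.0, 0.0), in_epithelium=in_epi,
            features={("m", "cell", "median"): median},
        )

    def test_mfi_is_mean_of_cell_medians(self):
        recs = [self._record("c", 1, 4.0, True), self._record("c", 2, 6.0, True)]
        spots = summarize_spot(recs, markers=["m"])
        epi = spots[spots.compartment_class == "epithelial"].iloc[0]
        assert epi.mfi == 5.0 and epi.n_cells == 2

    def test_empty_class_is_missing_not_zero(self):
        recs = [self._record("c", 1, 4.0, False), self._record("c", 2, 8.0, False)]
        spots = summarize_spot(recs, markers=["m"])
        epi = spots[spots.compartment_class == "epithelial"].iloc[0]
        stro = spots[spots.compartment_class == "stromal"].iloc[0]
        assert math.isnan(epi.mfi) and epi.n_cells == 0
        assert stro.mfi == 6.0 and stro.n_cells == 2

    def test_mixed_cores_rejected_and_order_invariance(self):
        recs = [self._record("a", 1, 4.0, True), self._record("b", 2, 6.0, True)]
        with pytest.raises(InputDataError):
            summarize_spot(recs, markers=["m"])
        recs = [self._record("c", i, float(v), i % 2 == 0)
                for i, v in enumerate((3, 1, 4, 1, 5, 9))]
        a = summarize_spot(recs, markers=["m"])
        b = summarize_spot(list(reversed(recs)), markers=["m"])
        pd.testing.assert_frame_equal(a.sort_values("compartment_class").reset_index(drop=True),
                                      b.sort_values("compartment_class").reset_index(drop=True))

    def test_noiseless_spot_mfi_matches_truth_oracle(self, segmented_noiseless):
        s = segmented_noiseless
        recs = measure_cells(s["core"], s["nuclei"], s["cells"], s["cytosols"], s["mask"])
        spots = summarize_spot(recs, markers=["NLRC4"])
        truth = s["truth"]
        expected = {
            True: np.mean([truth.per_cell_marker_means[k]["NLRC4"] + truth.background_level
                           for k in range(len(truth.in_epithelium)) if truth.in_epithelium[k]]),
            False: np.mean([truth.per_cell_marker_means[k]["NLRC4"] + truth.background_level
                            for k in range(len(truth.in_epithelium)) if not truth.in_epithelium[k]]),
        }
        epi = spots[spots.compartment_class == "epithelial"].iloc[0]
        stro = spots[spots.compartment_class == "stromal"].iloc[0]
        assert abs(epi.mfi - expected[True]) < 1e-9
        assert abs(stro.mfi - expected[False]) < 1e-9


class TestAggregatePatients:
    def spots(self, rows):
        return pd.DataFrame(rows, columns=["core_id", "marker", "compartment_class",
                                           "mfi", "n_cells"])

    def test_triplicate_mean_and_missing_tolerance(self):
        spot = self.spots([
            ("c1", "m", "epithelial", 10.0, 5),
            ("c2", "m", "epithelial", 12.0, 5),
            ("c3", "m", "epithelial", 14.0, 5),
            ("d1", "m", "epithelial", 10.0, 5),
            ("d2", "m", "epithelial", math.nan, 0),
            ("d3", "m", "epithelial", 14.0, 5),
            ("e1", "m", "epithelial", math.nan, 0),
        ])
        cmap = pd.DataFrame({
            "core_id": ["c1", "c2", "c3", "d1", "d2", "d3", "e1"],
            "patient_id": ["P1", "P1", "P1", "P2", "P2", "P2", "P3"],
        })
        clin = pd.DataFrame({"patient_id": ["P1", "P2", "P3"],
                             "os_months": [10, 20, 30], "event": [1, 0, 1]})
        out = aggregate_patients(spot, cmap, clin)
        vals = dict(zip(out.patient_id, out.m_epithelial))
        assert vals["P1"] == 12.0
        assert vals["P2"] == 12.0
        assert math.isnan(vals["P3"])

    def test_orphan_core_raises_listing_it(self):
        spot = self.spots([("cX", "m", "epithelial", 1.0, 1)])
        cmap = pd.DataFrame({"core_id": ["c1"], "patient_id": ["P1"]})
        clin = pd.DataFrame({"patient_id": ["P1"], "os_months": [1], "event": [1]})
        with pytest.raises(InputDataError, match="cX"):
            aggregate_patients(spot, cmap, clin)

    def test_cell_count_weighting_option(self):
        spot = self.spots([
            ("c1", "m", "epithelial", 10.0, 1),
            ("c2", "m", "epithelial", 20.0, 3),
        ])
        cmap = pd.DataFrame({"core_id": ["c1", "c2"], "patient_id": ["P1", "P1"]})
        clin = pd.DataFrame({"patient_id": ["P1"], "os_months": [1], "event": [1]})
        unw = aggregate_patients(spot, cmap, clin)
        wgt = aggregate_patients(spot, cmap, clin, weighting="cell_count")
        assert unw.m_epithelial.iloc[0] == 15.0
        assert wgt.m_epithelial.iloc[0] == 17.5

    def test_end_to_end_recovers_generating_patient_means(self):
        # 6 patients x 3 cores, tight cell-level spread: aggregated epithelial
        # MFI must track the generating per-patient mean (+ background)
        cfg = StudySimConfig(
            n_patients=6, cores_per_patient=3,
            core=CoreSimConfig(shape=(224, 224), n_nuclei=18, noise_sigma=3.0,
                               marker_cell_sd=2.0),
        )
        cores, cmap, clinical, truth = simulate_study(cfg, seed=13)
        from tmaquant.config import PipelineConfig
        from tmaquant.pipeline import quantify_core

        pipe_cfg = PipelineConfig()
        spot_frames = [quantify_core(core, pipe_cfg)[1] for core, _ in cores]
        patients = aggregate_patients(pd.concat(spot_frames, ignore_index=True),
                                      cmap, clinical)
        merged = patients.merge(truth, on="patient_id")
        bg = cfg.core.background_level
        err = (merged["NLRC4_epithelial"] - (merged["true_NLRC4_epithelial"] + bg)).abs()
        assert err.max() < 3.0


class TestCsvRoundTrip:
    def test_records_survive_write_read_exactly(self, tmp_path, segmented_noiseless):
        s = segmented_noiseless
        recs = measure_cells(s["core"], s["nuclei"], s["cells"], s["cytosols"], s["mask"])
        call_positivity(recs, [PositivityRule("NLRC4", [("NLRC4__cell__median", "ge", 100.0)])])
        from tmaquant import io as tio

        df = records_to_dataframe(recs)
        path = tmp_path / "cells.csv"
        tio.write_table(df, path)
        back = records_from_dataframe(tio.read_table(path))
        assert len(back) == len(recs)
        for a, b in zip(recs, back):
            assert a.core_id == b.core_id and a.cell_id == b.cell_id
            assert a.centroid == b.centroid
            assert a.in_epithelium == b.in_epithelium
            assert a.positivity == b.positivity
            for key, val in a.features.items():
                other = b.features[key]
                assert (math.isnan(val) and math.isnan(other)) or val == other
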