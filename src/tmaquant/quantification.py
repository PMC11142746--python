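"""Per-cell intensity features, positivity calls, spot MFI and patient values.

For every segmented cell the max / median / mean pixel intensity of each
channel is measured over three subcellular compartments (nucleus, cytosolic
ring, whole cell = their union). A cell is epithelial when its centroid
falls inside the cytokeratin mask. The spot-level readout is the MFI: the
arithmetic mean, over the cells of a compartment class, of each cell's
median whole-cell intensity. Patient values average the MFIs of replicate
cores (tumors are punched in triplicate), skipping missing replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
import pandas as pd

from .containers import Core, EpithelialMask, LabelMap
from .errors import ConfigurationError, InputDataError

COMPARTMENTS = ("cell", "nucleus", "cytosol")
STATISTICS = ("max", "median", "mean")


@dataclass
class CellFeatureRecord:
    """Feature bundle of one segmented cell.

    ``features`` maps ``(channel, compartment, statistic)`` to intensity;
    a compartment with zero pixels (ring fully contested) carries NaN.
    """

    core_id: str
    cell_id: int
    centroid: tuple[float, float]
    in_epithelium: bool
    features: dict[tuple[str, str, str], float]
    positivity: dict[str, bool] = field(default_factory=dict)
    positivity_flagged: dict[str, bool] = field(default_factory=dict)

    def feature(self, channel: str, compartment: str = "cell", statistic: str = "median") -> float:
        return self.features[(channel, compartment, statistic)]


@dataclass
class PositivityRule:
    """Conjunction of threshold clauses defining marker positivity.

    Each clause is ``(feature_key, op, threshold)`` with ``feature_key`` of
    the form ``"<channel>__<compartment>__<stat>"`` and ``op`` in
    {``ge``, ``lt``}; ``ge`` is inclusive. ``require_epithelium`` adds the
    in-cytokeratin-mask condition (counting cells positive for a marker and
    inside the mask).
    """

    marker: str
    clauses: list[tuple[str, str, float]]
    require_epithelium: bool = False


def _segment_stats(values):
    """Max/median/mean of one label's pixel values."""
    if values.size == 0:
        return {"max": math.nan, "median": math.nan, "mean": math.nan}
    return {
        "max": float(values.max()),
        "median": float(np.median(values)),
        "mean": float(values.mean()),
    }


def measure_cells(
    core: Core,
    nuclei: LabelMap,
    cells: LabelMap,
    cytosols: LabelMap,
    epithelium: EpithelialMask,
    membership: str = "centroid",
) -> list[CellFeatureRecord]:
    """Measure per-cell, per-compartment intensity statistics.

    The three label maps must share label ids (cell k = nucleus k +
    cytosol k) and the core's shape. The centroid is the whole-cell
    centroid; epithelial membership is centroid-in-mask (rounded to the
    nearest pixel) by default, or ``membership="majority"`` to call a cell
    epithelial when more than half of its pixels fall inside the mask.
    """
    if membership not in ("centroid", "majority"):
        raise ConfigurationError(f"membership must be 'centroid' or 'majority', got {membership!r}")
    maps = {"nucleus": nuclei, "cell": cells, "cytosol": cytosols}
    for name, lm in maps.items():
        if lm.labels.shape != core.shape:
            raise ConfigurationError(f"{name} label map shape differs from core")
    n = cells.n_objects
    if n == 0:
        return []

    chan_flat = {name: img.ravel() for name, img in core.channels.items()}
    per_label_values: dict[str, list] = {}
    for comp, lm in maps.items():
        flat = lm.labels.ravel()
        order = np.argsort(flat, kind="stable")
        sorted_labels = flat[order]
        starts = np.searchsorted(sorted_labels, np.arange(1, n + 2))
        per_label_values[comp] = (order, starts)

    # whole-cell centroids
    centroids = np.full((n, 2), np.nan)
    if n:
        coms = np.array(
            [[math.nan, math.nan] if c is None else list(c)
             for c in _centers_of_mass(cells.labels, n)]
        )
        centroids = coms

    mask = epithelium.mask
    mask_flat = mask.ravel()
    records: list[CellFeatureRecord] = []
    for k in range(1, n + 1):
        feats: dict[tuple[str, str, str], float] = {}
        cell_idx = None
        for comp in COMPARTMENTS:
            order, starts = per_label_values[comp]
            lo, hi = starts[k - 1], starts[k]
            idx = order[lo:hi]
            if comp == "cell":
                cell_idx = idx
            for ch, flat in chan_flat.items():
                stats = _segment_stats(flat[idx])
                for stat, val in stats.items():
                    feats[(ch, comp, stat)] = val
        r, c = centroids[k - 1]
        if membership == "centroid":
            ri = min(max(int(round(r)), 0), mask.shape[0] - 1)
            ci = min(max(int(round(c)), 0), mask.shape[1] - 1)
            inside = bool(mask[ri, ci])
        else:
            inside = bool(mask_flat[cell_idx].mean() > 0.5) if cell_idx.size else False
        records.append(
            CellFeatureRecord(
                core_id=core.core_id,
                cell_id=k,
                centroid=(float(r), float(c)),
                in_epithelium=inside,
                features=feats,
            )
        )
    return records


def _centers_of_mass(labels: np.ndarray, n: int):
    from scipy import ndimage

    return ndimage.center_of_mass(np.ones_like(labels), labels, index=range(1, n + 1))


def call_positivity(
    records: list[CellFeatureRecord], rules: list[PositivityRule]
) -> list[CellFeatureRecord]:
    """Evaluate positivity rules on every record (in place; also returned).

    A cell with a missing (NaN) referenced feature is called negative and
    flagged. A rule referencing a feature absent from the records raises
    ``ConfigurationError``.
    """
    if records:
        known = set(records[0].features)
    for rule in rules:
        parsed = []
        for key, op, thr in rule.clauses:
            parts = tuple(key.split("__"))
            if len(parts) != 3:
                raise ConfigurationError(
                    f"feature key {key!r} must be '<channel>__<compartment>__<stat>'"
                )
            if op not in ("ge", "lt"):
                raise ConfigurationError(f"unknown positivity operator {op!r}")
            if records and parts not in known:
                raise ConfigurationError(f"positivity rule references unknown feature {key!r}")
            parsed.append((parts, op, float(thr)))
        for rec in records:
            flagged = False
            result = True
            for parts, op, thr in parsed:
                val = rec.features[parts]
                if math.isnan(val):
                    result, flagged = False, True
                    break
                ok = val >= thr if op == "ge" else val < thr
                if not ok:
                    result = False
                    break
            if result and rule.require_epithelium and not rec.in_epithelium:
                result = False
            rec.positivity[rule.marker] = result
            rec.positivity_flagged[rule.marker] = flagged
    return records


def summarize_spot(
    records: list[CellFeatureRecord],
    markers: list[str],
    statistic_basis: tuple[str, str] = ("cell", "median"),
) -> pd.DataFrame:
    """Spot-level MFI: mean of per-cell medians, split by compartment class.

    Returns one row per (marker, class in {epithelial, stromal}) with the
    MFI and contributing cell count; a class with zero cells carries a
    missing MFI. All records must come from one core.
    """
    core_ids = {r.core_id for r in records}
    if len(core_ids) > 1:
        raise InputDataError(f"records from multiple cores: {sorted(core_ids)}")
    core_id = core_ids.pop() if core_ids else ""
    comp, stat = statistic_basis
    rows = []
    for marker in markers:
        for cls, flag in (("epithelial", True), ("stromal", False)):
            vals = [
                r.features[(marker, comp, stat)]
                for r in records
                if r.in_epithelium == flag
            ]
            vals_ok = [v for v in vals if not math.isnan(v)]
            rows.append(
                {
                    "core_id": core_id,
                    "marker": marker,
                    "compartment_class": cls,
                    "mfi": float(np.mean(vals_ok)) if vals_ok else math.nan,
                    "n_cells": len(vals),
                }
            )
    return pd.DataFrame(rows)


def aggregate_patients(
    spot_summaries: pd.DataFrame,
    core_map: pd.DataFrame,
    clinical: pd.DataFrame,
    weighting: str = "unweighted",
) -> pd.DataFrame:
    """Average replicate-core MFIs per patient and join the clinical table.

    The patient value for each (marker, class) is the unweighted mean of
    that patient's non-missing core MFIs (``weighting="cell_count"``
    weights replicates by their contributing cell counts instead); a
    patient whose replicates are all missing keeps a missing value. Cores
    absent from the core→patient map raise ``InputDataError`` listing the
    orphans. Output columns are ``<marker>_<class>`` next to the clinical
    fields.
    """
    if weighting not in ("unweighted", "cell_count"):
        raise ConfigurationError(f"unknown weighting {weighting!r}")
    cmap = dict(zip(core_map["core_id"], core_map["patient_id"]))
    orphans = sorted(set(spot_summaries["core_id"]) - set(cmap))
    if orphans:
        raise InputDataError(f"cores without a patient mapping: {orphans}")
    df = spot_summaries.copy()
    df["patient_id"] = df["core_id"].map(cmap)
    df["column"] = df["marker"] + "_" + df["compartment_class"]

    def _agg(sub: pd.DataFrame) -> float:
        ok = sub.dropna(subset=["mfi"])
        if ok.empty:
            return math.nan
        if weighting == "cell_count" and ok["n_cells"].sum() > 0:
            return float(np.average(ok["mfi"], weights=ok["n_cells"]))
        return float(ok["mfi"].mean())

    wide = (
        df.groupby(["patient_id", "column"])[["mfi", "n_cells"]]
        .apply(_agg)
        .unstack("column")
        .reset_index()
    )
    wide.columns.name = None
    missing_pat = sorted(set(wide["patient_id"]) - set(clinical["patient_id"]))
    if missing_pat:
        raise InputDataError(f"patients missing from the clinical table: {missing_pat}")
    return clinical.merge(wide, on="patient_id", how="left")


# --------------------------------------------------------------------------
# tabular (CSV-ready) views of per-cell records
# --------------------------------------------------------------------------

def records_to_dataframe(records: list[CellFeatureRecord]) -> pd.DataFrame:
    """One row per cell with ``<channel>__<compartment>__<stat>`` columns."""
    rows = []
    for r in records:
        row = {
            "core_id": r.core_id,
            "cell_id": r.cell_id,
            "centroid_row": r.centroid[0],
            "centroid_col": r.centroid[1],
            "in_epithelium": r.in_epithelium,
        }
        for (ch, comp, stat), val in r.features.items():
            row[f"{ch}__{comp}__{stat}"] = val
        for marker, pos in r.positivity.items():
            row[f"pos__{marker}"] = pos
        rows.append(row)
    return pd.DataFrame(rows)


def records_from_dataframe(df: pd.DataFrame) -> list[CellFeatureRecord]:
    feature_cols = [c for c in df.columns if c.count("__") == 2 and not c.startswith("pos__")]
    pos_cols = [c for c in df.columns if c.startswith("pos__")]
    records = []
    for _, row in df.iterrows():
        feats = {tuple(c.split("__")): float(row[c]) for c in feature_cols}
        rec = CellFeatureRecord(
            core_id=row["core_id"],
            cell_id=int(row["cell_id"]),
            centroid=(float(row["centroid_row"]), float(row["centroid_col"])),
            in_epithelium=bool(row["in_epithelium"]),
            features=feats,
            positivity={c[len("pos__"):]: bool(row[c]) for c in pos_cols},
        )
        records.append(rec)
    return records
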