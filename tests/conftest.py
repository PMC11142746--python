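import numpy as np
import pytest

from tmaquant.segmentation import build_cell_compartments, detect_epithelium, detect_nuclei
from tmaquant.synthetic import CoreSimConfig, simulate_core


@pytest.fixture(scope="session")
def noiseless_core():
    """A 50-nucleus noiseless core with its ground truth (shared, read-only)."""
    return simulate_core(CoreSimConfig(noise_sigma=0.0), seed=11)


@pytest.fixture(scope="session")
def segmented_noiseless(noiseless_core):
    """Full segmentation of the shared noiseless core."""
    core, truth = noiseless_core
    nuclei = detect_nuclei(core)
    cells, cytosols = build_cell_compartments(nuclei, 3.0, core.pixel_size_um)
    # zero morphology radii keep the detected mask pixel-identical to the
    # ground-truth region on noiseless input (values are exactly {bg, bg+amp})
    mask = detect_epithelium(core, closing_radius_um=0.0, opening_radius_um=0.0)
    return {"core": core, "truth": truth, "nuclei": nuclei, "cells": cells,
            "cytosols": cytosols, "mask": mask}


def match_centers_to_labels(centers: np.ndarray, labels: np.ndarray):
    """Greedy one-to-one match of ground-truth centers to label ids.

    Returns (true positives, n_detected, n_truth): a center scores a hit
    when it falls inside a not-yet-claimed label.
    """
    claimed = set()
    tp = 0
    for r, c in np.round(centers).astype(int):
        k = labels[r, c]
        if k > 0 and k not in claimed:
            claimed.add(k)
            tp += 1
    return tp, int(labels.max(initial=0)), len(centers)


def detection_f1(centers: np.ndarray, labels: np.ndarray) -> float:
    tp, n_det, n_true = match_centers_to_labels(centers, labels)
    prec = tp / n_det if n_det else 0.0
    rec = tp / n_true if n_true else 0.0
    return 2 * prec * rec / (prec + rec) if prec + rec else 0.0


def iou(a: np.ndarray, b: np.ndarray) -> float:
    union = (a | b).sum()
    return (a & b).sum() / union if union else 1.0
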