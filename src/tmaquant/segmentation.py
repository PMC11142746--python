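"""Epithelium and cell segmentation on one TMA core.

The epithelial ("cytokeratin") region is a simple intensity threshold on
the pan-cytokeratin channel cleaned by morphological opening then closing
with disk elements of physical radius. Nuclei are detected on the DAPI
channel by a difference-of-Gaussians band-pass, thresholding above
background, and a watershed split of touching clusters seeded on local
maxima. Whole cells are nuclei plus a fixed-width cytosolic ring; contested
ring pixels go to the nearest nucleus, ties to the lower label.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import closing, disk, opening
from skimage.segmentation import relabel_sequential, watershed

from .containers import Core, EpithelialMask, LabelMap
from .errors import ConfigurationError, DegenerateInputError


def _otsu_or_none(img: np.ndarray) -> float | None:
    if np.ptp(img) == 0:
        return None
    return float(threshold_otsu(img))


def detect_epithelium(
    core: Core,
    channel: str = "cytokeratin",
    threshold: float | str = "auto",
    closing_radius_um: float = 2.0,
    opening_radius_um: float = 1.0,
) -> EpithelialMask:
    """Threshold the cytokeratin channel and clean it morphologically.

    ``threshold="auto"`` uses Otsu on the raw channel. The binary image is
    opened then closed with disk structuring elements of the given physical
    radii (a radius that rounds to < 1 px skips that operation), which
    removes speckle and fills holes smaller than the closing element. The
    open-then-close filter is idempotent, so re-running the detector on its
    own (binarized) output reproduces the mask.
    """
    if closing_radius_um < 0 or opening_radius_um < 0:
        raise ConfigurationError("morphology radii must be >= 0")
    img = core.channel(channel)
    if threshold == "auto":
        thr = _otsu_or_none(img)
        if thr is None:
            raise DegenerateInputError(
                f"channel {channel!r} is constant; no foreground/background separation"
            )
    else:
        thr = float(threshold)
    binary = img >= thr
    r_open = int(round(core.um_to_px(opening_radius_um)))
    r_close = int(round(core.um_to_px(closing_radius_um)))
    if r_open >= 1:
        binary = opening(binary, disk(r_open))
    if r_close >= 1:
        binary = closing(binary, disk(r_close))
    return EpithelialMask(mask=binary, source="detected")


def detect_nuclei(
    core: Core,
    bandpass_sigmas_um: tuple[float, float] = (1.0, 8.0),
    background_offset: float | str = "auto",
    min_nucleus_area_um2: float = 10.0,
    seed_min_distance_um: float = 4.0,
) -> LabelMap:
    """Detect and label nuclei on the DAPI channel.

    Pipeline: difference of Gaussians with physical sigmas -> threshold
    (Otsu on the filtered image when ``"auto"``, else the given offset) ->
    8-connected components -> watershed split seeded on local maxima of the
    smoothed DAPI with a minimum seed separation -> removal of objects below
    the minimum area -> consecutive relabeling from 1.

    A blank (constant) DAPI channel yields an empty label map, not an error.
    """
    s_lo, s_hi = bandpass_sigmas_um
    if not (0 < s_lo < s_hi):
        raise ConfigurationError(f"band-pass sigmas must satisfy 0 < low < high, got {bandpass_sigmas_um}")
    dapi = np.asarray(core.channel("DAPI"), dtype=float)
    empty = LabelMap(labels=np.zeros(dapi.shape, dtype=np.int32), kind="nucleus")
    if np.ptp(dapi) == 0:
        return empty

    px_lo = core.um_to_px(s_lo)
    px_hi = core.um_to_px(s_hi)
    smooth_lo = gaussian(dapi, sigma=px_lo, preserve_range=True)
    band = smooth_lo - gaussian(dapi, sigma=px_hi, preserve_range=True)
    if background_offset == "auto":
        thr = _otsu_or_none(band)
        if thr is None:
            return empty
    else:
        thr = float(background_offset)
    fg = band > thr
    if not fg.any():
        return empty

    min_sep_px = max(int(round(core.um_to_px(seed_min_distance_um))), 1)
    peaks = peak_local_max(
        smooth_lo, min_distance=min_sep_px, labels=fg, exclude_border=False
    )
    markers = np.zeros(dapi.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        # foreground without a usable seed: fall back to plain components
        labels, _ = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    else:
        labels = watershed(-smooth_lo, markers=markers, mask=fg, connectivity=2)

    min_area_px = min_nucleus_area_um2 / core.pixel_size_um**2
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_area_px)
    if small.size:
        labels[np.isin(labels, small[small > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    return LabelMap(labels=labels.astype(np.int32), kind="nucleus")


def build_cell_compartments(
    nuclei: LabelMap, ring_width_um: float, pixel_size_um: float
) -> tuple[LabelMap, LabelMap]:
    """Grow a fixed-width cytosolic ring around every nucleus.

    Each nucleus is dilated by the ring width (Euclidean distance, so a
    1-px ring reaches the 4-neighborhood); pixels claimed by several nuclei
    go to the one whose footprint is nearest, ties to the lower label id.
    Returns ``(cells, cytosols)`` where cell k = nucleus k union cytosol k
    and label ids correspond across the three maps.
    """
    if nuclei.kind != "nucleus":
        raise ConfigurationError("build_cell_compartments expects a nucleus label map")
    if ring_width_um <= 0:
        raise ConfigurationError("ring_width_um must be > 0")
    lab = nuclei.labels
    ring_px = ring_width_um / pixel_size_um
    pad = int(math.ceil(ring_px)) + 1
    best_dist = np.full(lab.shape, np.inf)
    best_label = np.zeros(lab.shape, dtype=np.int32)
    objects = ndimage.find_objects(lab)
    for k, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        rsl = slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, lab.shape[0]))
        csl = slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, lab.shape[1]))
        crop = lab[rsl, csl]
        d = ndimage.distance_transform_edt(crop != k)
        upd = d < best_dist[rsl, csl]  # strict: earlier (lower) label keeps ties
        bd = best_dist[rsl, csl]
        bl = best_label[rsl, csl]
        bd[upd] = d[upd]
        bl[upd] = k
        best_dist[rsl, csl] = bd
        best_label[rsl, csl] = bl
    cells = np.where(best_dist <= ring_px + 1e-9, best_label, 0).astype(np.int32)
    cytosols = np.where(lab == 0, cells, 0).astype(np.int32)
    return LabelMap(labels=cells, kind="cell"), LabelMap(labels=cytosols, kind="cytosol")
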