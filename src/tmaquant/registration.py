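"""Rigid registration of consecutive TMA sections via their DAPI channels.

Serial 5-um sections keep nearly the same nuclear layout, so a rotation
plus translation suffices. The rotation is found by a coarse grid search
(each candidate angle scored after solving the translation by phase
correlation) followed by a fine local grid; the similarity metric is the
normalized cross-correlation (NCC) of background-subtracted DAPI over the
in-frame overlap. The identity transform is always scored too, so the
returned transform never does worse than not registering at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .containers import Core, EpithelialMask
from .errors import DegenerateInputError, RegistrationConfidenceError
from .transforms import RigidTransform2D


@dataclass
class RegistrationConfig:
    rotation_range_deg: float = 20.0
    coarse_step_deg: float = 1.0
    fine_step_deg: float = 0.1
    upsample_factor: int = 20
    min_score: float = 0.2  # below this the transform is not trusted


def apply_transform(
    image: np.ndarray, transform: RigidTransform2D, interpolation: str = "linear"
) -> np.ndarray:
    """Resample ``image`` under the rigid transform.

    Out-of-frame pixels become 0. ``nearest`` interpolation preserves the
    input's value set and is mandatory for masks and label maps; the
    identity transform returns the input values unchanged.
    """
    order = {"linear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise ValueError(f"interpolation must be 'linear' or 'nearest', got {interpolation!r}")
    img = np.asarray(image)
    matrix, offset = transform.inverse_map(img.shape)
    out = ndimage.affine_transform(
        img.astype(float), matrix, offset=offset, order=order, mode="constant", cval=0.0
    )
    if order == 0:
        out = out.astype(img.dtype)
    return out


def _prep(dapi: np.ndarray) -> np.ndarray:
    x = np.asarray(dapi, dtype=float)
    return x - np.median(x)  # background subtraction; keeps NCC shift-invariant


def _ncc(fixed: np.ndarray, moved: np.ndarray, valid: np.ndarray) -> float:
    a = fixed[valid]
    b = moved[valid]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _score(fixed: np.ndarray, moving: np.ndarray, t: RigidTransform2D) -> float:
    moved = apply_transform(moving, t, interpolation="linear")
    valid = apply_transform(np.ones_like(moving), t, interpolation="nearest") > 0.5
    if valid.sum() < 16:
        return -1.0
    return _ncc(fixed, moved, valid)


def _best_at_angle(
    fixed: np.ndarray, moving: np.ndarray, angle: float, upsample: int
) -> tuple[RigidTransform2D, float]:
    rotated = apply_transform(moving, RigidTransform2D(angle, (0.0, 0.0)), "linear")
    shift, _, _ = phase_cross_correlation(fixed, rotated, upsample_factor=upsample,
                                          normalization=None)
    t = RigidTransform2D(angle, (float(shift[0]), float(shift[1])))
    return t, _score(fixed, moving, t)


def estimate_rigid(
    fixed: Core, moving: Core, config: RegistrationConfig | None = None
) -> tuple[RigidTransform2D, float]:
    """Estimate the transform that maps ``moving`` onto ``fixed``.

    Applying the returned transform to any channel of ``moving`` aligns it
    with ``fixed``. The second return value is the NCC similarity in
    [-1, 1] of the aligned pair. Raises ``DegenerateInputError`` for
    constant DAPI and ``RegistrationConfidenceError`` (carrying the score)
    when no candidate reaches ``config.min_score``.
    """
    cfg = config or RegistrationConfig()
    f = _prep(fixed.channel("DAPI"))
    m = _prep(moving.channel("DAPI"))
    if f.shape != m.shape:
        raise DegenerateInputError("fixed and moving DAPI channels differ in shape")
    if np.ptp(f) == 0 or np.ptp(m) == 0:
        raise DegenerateInputError("constant DAPI channel: nothing to register")

    best_t, best_s = RigidTransform2D.identity(), _score(f, m, RigidTransform2D.identity())
    n = int(round(cfg.rotation_range_deg / cfg.coarse_step_deg))
    for angle in np.linspace(-cfg.rotation_range_deg, cfg.rotation_range_deg, 2 * n + 1):
        t, s = _best_at_angle(f, m, float(angle), cfg.upsample_factor)
        if s > best_s:
            best_t, best_s = t, s
    lo = best_t.rotation_deg - cfg.coarse_step_deg
    hi = best_t.rotation_deg + cfg.coarse_step_deg
    n_fine = int(round((hi - lo) / cfg.fine_step_deg))
    for angle in np.linspace(lo, hi, n_fine + 1):
        t, s = _best_at_angle(f, m, float(angle), cfg.upsample_factor)
        if s > best_s:
            best_t, best_s = t, s
    if best_s < cfg.min_score:
        raise RegistrationConfidenceError("registration similarity below threshold", best_s)
    return best_t, best_s


def transfer_mask(mask: EpithelialMask, transform: RigidTransform2D) -> EpithelialMask:
    """Warp an epithelial mask onto a consecutive section.

    Nearest-neighbor resampling then re-binarization keeps the result
    strictly boolean; the transform is recorded on the output.
    """
    warped = apply_transform(mask.mask.astype(np.uint8), transform, "nearest") > 0
    return EpithelialMask(mask=warped, source="transferred", transform=transform)
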