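"""Rigid (rotation + translation) transforms between serial TMA sections.

Conventions
-----------
Coordinates are 0-based ``(row, col)`` with the origin at the top-left pixel
center. A transform rotates by ``rotation_deg`` about the image center
``c = ((H-1)/2, (W-1)/2)`` and then translates by ``translation_px``::

    p' = R(theta) @ (p - c) + c + t

``R(theta)`` acts in the (row, col) plane, i.e. ``row' = cos*row - sin*col``
up to the centering; a positive angle therefore appears clockwise on screen
(the row axis points down). Because consecutive sections share a frame, the
composition of two such transforms is again a rotation about the same
center plus a translation, so composition and inversion have closed forms
that do not depend on the image shape.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
import math

import numpy as np


def _rot2(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s], [s, c]], dtype=float)


@dataclass(frozen=True)
class RigidTransform2D:
    """Rotation about the image center followed by a translation."""

    rotation_deg: float
    translation_px: tuple[float, float]  # (d_row, d_col)

    @staticmethod
    def identity() -> "RigidTransform2D":
        return RigidTransform2D(0.0, (0.0, 0.0))

    # ---- group operations -------------------------------------------------

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Return the transform that applies ``self`` first, then ``other``.

        ``compose(A, B).apply(p) == B.apply(A.apply(p))``.
        """
        rot = self.rotation_deg + other.rotation_deg
        t = _rot2(other.rotation_deg) @ np.asarray(self.translation_px) + np.asarray(
            other.translation_px
        )
        return RigidTransform2D(rot, (float(t[0]), float(t[1])))

    def invert(self) -> "RigidTransform2D":
        t = -(_rot2(-self.rotation_deg) @ np.asarray(self.translation_px))
        return RigidTransform2D(-self.rotation_deg, (float(t[0]), float(t[1])))

    # ---- application ------------------------------------------------------

    def apply_to_points(self, points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
        """Map an ``(N, 2)`` array of (row, col) points through the transform."""
        c = np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = (pts - c) @ _rot2(self.rotation_deg).T + c + np.asarray(self.translation_px)
        return out

    def inverse_map(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Matrix/offset pair such that ``input_coord = matrix @ out_coord + offset``.

        This is the pull-back map consumed by ``scipy.ndimage.affine_transform``
        when resampling an image under this transform.
        """
        c = np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])
        rinv = _rot2(-self.rotation_deg)
        offset = c - rinv @ (c + np.asarray(self.translation_px))
        return rinv, offset

    # ---- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "rotation_deg": self.rotation_deg,
            "d_row": self.translation_px[0],
            "d_col": self.translation_px[1],
        }

    @staticmethod
    def from_dict(d: dict) -> "RigidTransform2D":
        return RigidTransform2D(float(d["rotation_deg"]), (float(d["d_row"]), float(d["d_col"])))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @staticmethod
    def from_json(path) -> "RigidTransform2D":
        with open(path) as fh:
            return RigidTransform2D.from_dict(json.load(fh))
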