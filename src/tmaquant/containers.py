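"""In-memory containers shared across the pipeline stages.

A ``Core`` is one TMA spot: a stack of co-registered 2-D fluorescence
channels indexed by name, with a physical pixel size. Masks and label maps
always share their core's shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigurationError
from .transforms import RigidTransform2D


@dataclass
class Core:
    """Multi-channel image of one TMA spot.

    Parameters
    ----------
    channels
        Mapping channel name -> 2-D float array (arbitrary fluorescence
        units, non-negative). All channels share one shape.
    pixel_size_um
        Physical pixel pitch in micrometers per pixel.
    core_id
        Identifier linking the spot to the core→patient map.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    core_id: str = ""

    def __post_init__(self):
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ConfigurationError(f"channels of core {self.core_id!r} differ in shape: {shapes}")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise ConfigurationError(
                f"core {self.core_id!r} has no channel {name!r}; available: {sorted(self.channels)}"
            ) from None

    def um_to_px(self, length_um: float) -> float:
        return length_um / self.pixel_size_um


@dataclass
class EpithelialMask:
    """Boolean cytokeratin (epithelium) mask for one core.

    ``source`` records whether the mask was detected on this section or
    transferred from a consecutive one; transferred masks keep the rigid
    transform that produced them.
    """

    mask: np.ndarray
    source: str = "detected"  # {"detected", "transferred"}
    transform: Optional[RigidTransform2D] = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.source not in ("detected", "transferred"):
            raise ConfigurationError(f"unknown mask source {self.source!r}")
        if self.source == "transferred" and self.transform is None:
            raise ConfigurationError("transferred mask must record its transform")


@dataclass
class LabelMap:
    """Integer object labels over a core (0 = background, k >= 1 = object k).

    ``kind`` distinguishes nuclei, whole cells (nucleus + ring) and cytosolic
    rings; the three maps of one core share label ids so that cell k is
    nucleus k plus cytosol k.
    """

    labels: np.ndarray
    kind: str  # {"nucleus", "cell", "cytosol"}

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ConfigurationError("label map must be integer-typed")
        if self.kind not in ("nucleus", "cell", "cytosol"):
            raise ConfigurationError(f"unknown label-map kind {self.kind!r}")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max(initial=0))

    def footprint(self, k: int) -> np.ndarray:
        return self.labels == k
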