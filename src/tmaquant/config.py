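"""Pipeline configuration: one dataclass block per stage, loaded from YAML.

Unknown keys are rejected so typos fail loudly; every run writes the fully
resolved configuration next to its outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .errors import ConfigurationError


def _build(cls, data: dict, context: str):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{context}: expected a mapping, got {type(data).__name__}")
    known = {f.name for f in fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigurationError(f"{context}: unknown keys {unknown} (known: {sorted(known)})")
    kwargs = {}
    for f in fields(cls):
        if f.name in data:
            val = data[f.name]
            if isinstance(val, list) and f.name in _TUPLE_FIELDS:
                val = tuple(val)
            kwargs[f.name] = val
    return cls(**kwargs)


_TUPLE_FIELDS = {"bandpass_sigmas_um", "combine"}


@dataclass
class ChannelConfig:
    dapi: str = "DAPI"
    cytokeratin: str = "cytokeratin"
    markers: list[str] = field(default_factory=lambda: ["NLRC4"])


@dataclass
class SegmentationConfig:
    threshold: float | str = "auto"            # cytokeratin threshold
    closing_radius_um: float = 2.0
    opening_radius_um: float = 1.0
    bandpass_sigmas_um: tuple[float, float] = (1.0, 8.0)
    background_offset: float | str = "auto"    # DAPI band-pass threshold
    min_nucleus_area_um2: float = 10.0
    seed_min_distance_um: float = 4.0
    ring_width_um: float = 3.0


@dataclass
class RegistrationBlock:
    enabled: bool = False
    rotation_range_deg: float = 20.0
    coarse_step_deg: float = 1.0
    fine_step_deg: float = 0.1
    min_score: float = 0.2


@dataclass
class QuantificationConfig:
    membership: str = "centroid"        # or "majority"
    weighting: str = "unweighted"       # or "cell_count"


@dataclass
class StratificationConfig:
    # cutoff method per marker; markers not listed use default_method
    methods: dict = field(default_factory=dict)
    default_method: str = "roc"
    compartment_class: str = "epithelial"
    combine: tuple[str, str] | None = None
    horizons: list[float] = field(default_factory=lambda: [60.0])


@dataclass
class SimulateConfig:
    n_patients: int = 12
    cores_per_patient: int = 3
    image_size: int = 256
    n_nuclei: int = 25
    noise_sigma: float = 5.0
    hazard_ratio: float = 0.44
    baseline_median_survival: float = 56.98
    marker_effect: float = 40.0
    censoring_rate: float = 0.2


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "tmaquant-out"
    pixel_size_um: float = 0.46        # fallback when image metadata lacks it
    channels: ChannelConfig = field(default_factory=ChannelConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    registration: RegistrationBlock = field(default_factory=RegistrationBlock)
    quantification: QuantificationConfig = field(default_factory=QuantificationConfig)
    stratification: StratificationConfig = field(default_factory=StratificationConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    @staticmethod
    def from_dict(data: dict) -> "PipelineConfig":
        data = dict(data or {})
        blocks = {
            "channels": ChannelConfig,
            "segmentation": SegmentationConfig,
            "registration": RegistrationBlock,
            "quantification": QuantificationConfig,
            "stratification": StratificationConfig,
            "simulate": SimulateConfig,
        }
        kwargs = {}
        for name, cls in blocks.items():
            if name in data:
                kwargs[name] = _build(cls, data.pop(name), name)
        top = _build(PipelineConfig, data, "pipeline")
        for name, val in kwargs.items():
            setattr(top, name, val)
        return top

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            return PipelineConfig.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def cutoff_method(self, marker: str) -> str:
        method = self.stratification.methods.get(marker, self.stratification.default_method)
        if method not in ("roc", "median"):
            raise ConfigurationError(f"unknown cutoff method {method!r} for {marker!r}")
        return method
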