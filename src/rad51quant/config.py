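"""YAML-backed pipeline configuration.

All tunable parameters of the imaging and NMR pipelines live in one
nested configuration object that round-trips through YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .quantify import BrightnessThresholds
from .segmentation import SegmentationParams
from .synthetic import AcquisitionParams

__all__ = [
    "SkeletonConfig", "ClassificationConfig", "StatisticsConfig",
    "NMRConfig", "SimulateConfig", "PipelineConfig",
]


@dataclass
class SkeletonConfig:
    min_branch_px: float | None = None  # default: 2 * segmentation width_px
    measurement_dilation_px: int = 6    # mask growth when summing intensities

    def resolved_min_branch(self, width_px: float) -> float:
        return 2.0 * width_px if self.min_branch_px is None else float(self.min_branch_px)


@dataclass
class ClassificationConfig:
    wt_strain: str = "WT"
    bright_cut: float = 0.80
    dim_cut: float = 0.20
    reference: str = "wt_foci_mean"

    def thresholds(self) -> BrightnessThresholds:
        return BrightnessThresholds(self.bright_cut, self.dim_cut, self.reference)


@dataclass
class StatisticsConfig:
    pairs: tuple = ()        # () = all unordered strain pairs
    models: tuple = ("M1", "M2", "M3")
    alpha: float = 0.05
    use_t: bool = True       # t reference with residual df; False = normal


@dataclass
class NMRConfig:
    threshold: float = 0.5
    min_run: int = 5
    max_gap: int = 3
    disorder_cutoff_ppm: float = 0.5
    start_residue: int = 1
    rc_table: str = ""       # optional CSV replacing the built-in coil table


@dataclass
class SimulateConfig:
    n_cells: int = 125
    n_batches: int = 3


@dataclass
class PipelineConfig:
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    skeleton: SkeletonConfig = field(default_factory=SkeletonConfig)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    statistics: StatisticsConfig = field(default_factory=StatisticsConfig)
    nmr: NMRConfig = field(default_factory=NMRConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        import numbers

        if not isinstance(self.seed, numbers.Integral):
            raise ValueError("seed must be an integer")
        self.seed = int(self.seed)
        if self.nmr.rc_table and not Path(self.nmr.rc_table).exists():
            raise ValueError(f"random-coil table not found: {self.nmr.rc_table}")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_listify(self.to_dict()), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = {}
        sections = {
            "acquisition": AcquisitionParams,
            "segmentation": SegmentationParams,
            "skeleton": SkeletonConfig,
            "classification": ClassificationConfig,
            "statistics": StatisticsConfig,
            "nmr": NMRConfig,
            "simulate": SimulateConfig,
        }
        for name, klass in sections.items():
            if name in raw:
                kwargs[name] = _build(klass, raw[name])
        for scalar in ("seed", "outdir"):
            if scalar in raw:
                kwargs[scalar] = raw[scalar]
        return cls(**kwargs)

    def content_hash(self) -> str:
        text = yaml.safe_dump(_listify(self.to_dict()), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _build(klass, section: dict):
    """Instantiate a dataclass from a YAML mapping, restoring tuples."""
    fields = {f.name: f for f in dataclasses.fields(klass)}
    unknown = set(section) - set(fields)
    if unknown:
        raise ValueError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in section.items():
        default = fields[key].default
        if isinstance(value, list):
            value = _tuplify(value)
        kwargs[key] = value
    return klass(**kwargs)


def _tuplify(value):
    if isinstance(value, list):
        return tuple(_tuplify(v) for v in value)
    return value


def _listify(value):
    if isinstance(value, dict):
        return {k: _listify(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_listify(v) for v in value]
    return value
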