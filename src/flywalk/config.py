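"""Pipeline configuration: one nested dataclass per stage, YAML round-trip.

Every threshold used anywhere in the pipeline lives here so that a batch
run is fully reproducible from the config file alone.  Unknown keys in a
config file are rejected rather than silently ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class QCConfig:
    min_valid_frames: int = 3
    focus_threshold: float = 100.0
    border_margin: int = 2
    fg_diff_threshold: float = 40.0
    saturation_level: int = 250
    reflection_max_frac: float = 0.005
    max_axis_angle_deg: float = 10.0
    min_wing_body_ratio: float = 0.3
    symmetry_min_iou: float = 0.85
    min_mask_area: int = 500
    body_level_max: float = 80.0
    wing_level_range: tuple[float, float] = (110.0, 205.0)


@dataclass
class BodyConfig:
    projection_percentile: float = 95.0
    closing_radius: int = 2
    min_marker_separation: int = 45
    min_body_area: int = 3000
    thorax_reference_width_px: float = 90.0


@dataclass
class SexConfig:
    n_samples: int = 100
    tau_comb: float = 0.3
    tau_lum: float = 0.15
    eccentricity_max: float = 0.95
    comb_level_range: tuple[float, float] = (25.0, 60.0)
    leg_level_min: float = 80.0
    comb_area_range: tuple[float, float] = (3.0, 40.0)
    comb_area_ref: float = 8.0
    min_abdomen_area: int = 500


@dataclass
class HeadConfig:
    roi_margin: int = 5
    ocelli_min_corr: float = 0.5
    edge_threshold: float = 12.0
    scan_step: float = 0.5
    smooth_sigma_px: float = 1.0
    template_separation_px: float = 12.0


@dataclass
class WingConfig:
    clahe_clip_limit: float = 2.0
    clahe_tiles: int = 8
    blue_structure_range: tuple[float, float] = (85.0, 105.0)
    red_structure_max: float = 55.0
    min_membrane_area: int = 500
    boundary_exclude_px: int = 2
    side_margin_px: int = 8
    fit_iterations: int = 2
    fit_tol_px: float = 0.1
    trim_distance_px: float = 15.0
    outline_knots: int = 12
    vein_knots: int = 6


@dataclass
class SelectConfig:
    criterion: str = "wa/sw^2"
    n_top: int = 10
    n_bottom: int = 10
    n_wells: int = 182


@dataclass
class PipelineConfig:
    mm_per_px: float = 0.0087
    seed: int = 0
    overlay: bool = False
    log_level: str = "INFO"
    qc: QCConfig = field(default_factory=QCConfig)
    body: BodyConfig = field(default_factory=BodyConfig)
    sex: SexConfig = field(default_factory=SexConfig)
    head: HeadConfig = field(default_factory=HeadConfig)
    wing: WingConfig = field(default_factory=WingConfig)
    select: SelectConfig = field(default_factory=SelectConfig)

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _build(cls, data, context="")

    def to_yaml(self, path: str | Path) -> None:
        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj

        Path(path).write_text(yaml.safe_dump(_clean(self.to_dict()), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)


def _build(cls, data: dict, context: str):
    """Construct dataclass ``cls`` from ``data``, rejecting unknown keys."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        where = context or cls.__name__
        raise KeyError(f"unknown config key(s) in {where}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        sub = _SUBCONFIGS.get(name)
        if sub is not None and isinstance(value, dict):
            kwargs[name] = _build(sub, value, context=name)
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_SUBCONFIGS = {
    "qc": QCConfig,
    "body": BodyConfig,
    "sex": SexConfig,
    "head": HeadConfig,
    "wing": WingConfig,
    "select": SelectConfig,
}
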