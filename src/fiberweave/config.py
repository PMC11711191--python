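"""Pipeline configuration: every stage parameter with its standard default,
serializable to and from YAML as a fixed point."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All stage parameters of the end-to-end pipeline.

    Defaults are the analysis's standard settings: display clip (0, 4000),
    blur σ = 0.5 px, rolling-ball radius 40 px, ten 200 × 250 μm intensity
    ROIs, four 600 × 450 μm orientation ROIs, 150 px boundary margins,
    ±5° angle windows, and a 200 × 200 px × 100 μm crossing ROI at a
    1.21 × 1.21 × 10.62 μm voxel.
    """

    seed: int = 0
    out_dir: str = "fiberweave_out"

    # synthesis (optional stage)
    synthesize: bool = True
    n_fibers: int = 80
    mixture_weights: tuple = (0.25, 0.25, 0.5)
    fiber_radius_um: float = 5.0
    planted_crossing_count: int = 0
    intensity_scale: float = 600.0
    intensity_ratio: float = 2.0
    noise_sigma_frac: float = 0.05
    stack_shape_px: tuple = (4, 512, 512)
    layer_thickness_mm: dict = field(
        default_factory=lambda: {"SC": 0.39, "VE": 0.05, "D": 0.8}
    )
    boundary_undulation_mm: float = 0.05
    mask_width_px: int = 1000
    mask_pixel_size_mm: float = 0.01

    # units
    voxel_um: tuple = (10.62, 1.21, 1.21)

    # preprocessing
    clip: tuple = (0.0, 4000.0)
    blur_sigma_px: float = 0.5
    ball_radius_px: float = 40.0

    # intensity
    intensity_n_rois: int = 10
    intensity_roi_um: tuple = (200.0, 250.0)
    intensity_margin_px: int = 150

    # orientation
    orient_n_rois: int = 4
    orient_roi_um: tuple = (600.0, 450.0)
    orient_margin_px: int = 150
    perp_halfwidth_deg: float = 5.0
    par_halfwidth_deg: float = 5.0
    keep_fraction: float = 0.06
    min_length_um: float = 20.0

    # entanglement
    crossing_roi_px: tuple = (200, 200)
    crossing_depth_um: float = 100.0
    min_cross_angle_deg: float = 15.0

    # stage inputs when synthesis is disabled
    input_stacks: dict = field(default_factory=dict)
    input_masks: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for k, v in d.items():
            if k not in fields:
                raise ValueError(f"unknown config key {k!r}")
            if isinstance(v, list) and not isinstance(fields[k].default, list) \
                    and fields[k].name not in ("input_masks",):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, src) -> "PipelineConfig":
        """Parse a config from a YAML file path or a YAML string."""
        is_pathlike = isinstance(src, Path) or (
            isinstance(src, str) and "\n" not in src and len(src) < 1000
            and Path(src).exists()
        )
        text = Path(src).read_text() if is_pathlike else str(src)
        return cls.from_dict(yaml.safe_load(text) or {})
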