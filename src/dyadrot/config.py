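"""Run configuration for the rotation-analysis pipeline.

All internal computation is carried out in micrometres, degrees and
minutes.  Inputs recorded in pixels are converted on read using
``unit_scale_um_per_px``; the imaging pixel size is acquisition-specific
and therefore has no meaningful default, so pixel-space inputs must set
it explicitly (``pixel_input=True``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Parameters shared across the analysis stages.

    Attributes
    ----------
    frame_interval_s:
        Acquisition interval between consecutive frames, seconds.
    max_observation_min:
        Observation window; tracked points beyond this time are dropped.
    pre_division_frames:
        Frames kept before the progenitor division in segmentation exports.
    post_division_frames_min:
        Minimum frames required after division for a usable recording.
    critical_angle_deg:
        Rotations with a final absolute cumulative angle strictly above
        this threshold count as positional inversions.
    noise_frame_cap:
        Only the first ``noise_frame_cap`` frames enter the trajectory
        noise statistic.
    min_displacement_um:
        Pairs where either cell's net displacement over the noise window
        is below this are excluded from the noise statistic.
    noise_aggregation:
        ``"pooled"`` divides the summed path lengths of the two cells by
        their summed chords; ``"mean_ratio"`` averages the per-cell
        path/chord ratios.
    pixel_input / unit_scale_um_per_px:
        Whether coordinates (and areas/lengths) arrive in pixels, and
        the micrometres-per-pixel conversion factor to apply.
    """

    frame_interval_s: float = 200.0
    max_observation_min: float = 500.0
    pre_division_frames: int = 10
    post_division_frames_min: int = 70
    critical_angle_deg: float = 90.0
    noise_frame_cap: int = 200
    min_displacement_um: float = 2.0
    noise_aggregation: str = "pooled"
    pixel_input: bool = False
    unit_scale_um_per_px: float | None = None
    interface_tau_s: float = 0.05
    interface_tau_c: float = 0.05
    loess_span: float = 0.3
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("frame_interval_s", "max_observation_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.critical_angle_deg < 180.0):
            raise ValueError("critical_angle_deg must lie in (0, 180)")
        if self.noise_aggregation not in ("pooled", "mean_ratio"):
            raise ValueError("noise_aggregation must be 'pooled' or 'mean_ratio'")
        if self.pixel_input and not self.unit_scale_um_per_px:
            raise ValueError(
                "pixel_input requires an explicit unit_scale_um_per_px; "
                "the pixel size is acquisition-specific and has no default"
            )

    @property
    def frame_interval_min(self) -> float:
        return self.frame_interval_s / 60.0

    @property
    def scale(self) -> float:
        """Factor applied to raw coordinates to obtain micrometres."""
        return self.unit_scale_um_per_px if self.pixel_input else 1.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in data.items() if k in known}
        kwargs.setdefault("extras", {})
        kwargs["extras"].update({k: v for k, v in data.items() if k not in known})
        return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Read a :class:`RunConfig` from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return RunConfig.from_dict(data)
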