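"""Session configuration: geometry, thresholds and area mapping from YAML."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fusion import DEFAULT_AREA_MAPPING
from .geometry import MicArrayGeometry

__all__ = ["SessionConfig", "load_config"]


@dataclass(frozen=True)
class SessionConfig:
    """Everything the monitoring pipeline needs besides the audio itself.

    Defaults reproduce the deployed system: +/-30 deg effective window,
    confidence threshold 0.5 (strict), 1 s frames, Grubbs alpha 0.05.
    """

    geometry_A: MicArrayGeometry = field(default_factory=MicArrayGeometry)
    geometry_B: MicArrayGeometry = field(default_factory=MicArrayGeometry)
    area_mapping: dict = field(default_factory=lambda: dict(DEFAULT_AREA_MAPPING))
    angle_limit: float = 30.0
    conf_threshold: float = 0.5
    grubbs_alpha: float = 0.05
    frame_seconds: float = 1.0
    energy_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.angle_limit <= 0 or self.conf_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.frame_seconds <= 0 or not 0 < self.grubbs_alpha < 1:
            raise ValueError("bad frame length or Grubbs alpha")


def _geometry_from_dict(d: dict) -> MicArrayGeometry:
    kwargs = {}
    if "mic_positions" in d:
        kwargs["mic_positions"] = tuple(float(p) for p in d["mic_positions"])
    if "solver_triple" in d:
        kwargs["solver_triple"] = tuple(int(i) for i in d["solver_triple"])
    if "sound_speed" in d:
        kwargs["c"] = float(d["sound_speed"])
    return MicArrayGeometry(**kwargs)


def load_config(path: str | Path) -> SessionConfig:
    """Load a YAML session config; absent keys keep their defaults.

    Layout::

        geometry:            # or geometry_A / geometry_B for distinct arrays
          mic_positions: [0.0, 0.149, 0.189, 0.226]
          solver_triple: [0, 1, 3]
          sound_speed: 340.0
        area_mapping: {"++": I, "-+": II, "--": III, "+-": IV}
        angle_limit: 30.0
        conf_threshold: 0.5
        grubbs_alpha: 0.05
        frame_seconds: 1.0
        energy_threshold: 0.0
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    if "geometry" in raw:
        g = _geometry_from_dict(raw["geometry"])
        kwargs["geometry_A"] = g
        kwargs["geometry_B"] = g
    for key in ("geometry_A", "geometry_B"):
        if key in raw:
            kwargs[key] = _geometry_from_dict(raw[key])
    if "area_mapping" in raw:
        kwargs["area_mapping"] = {
            (k[0], k[1]): str(v) for k, v in raw["area_mapping"].items()
        }
    for key in ("angle_limit", "conf_threshold", "grubbs_alpha",
                "frame_seconds", "energy_threshold"):
        if key in raw:
            kwargs[key] = float(raw[key])
    return SessionConfig(**kwargs)
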