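"""Run configuration: every tunable symbol in one serializable object.

The on-disk form is a small YAML (or JSON) mapping whose keys mirror the
circuit symbol names (I_A .. I_D, a..d, C1_pF, C2_pF under ``oscillator``;
I_G, I_F, I_GI, I_E, g under ``excitation``; dt_us, t_max_us, seed under
``simulation``; the readout and tiling options under their own sections).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .model import DEFAULT_DT_US, DEFAULT_RAIL_V, OscillatorParams
from .network import (DEFAULT_RECORD_STRIDE, DEFAULT_STOP_OS_PHASES,
                      DEFAULT_T_MAX_US, ExcitationParams)
from .labeling import DEFAULT_SYNC_THRESHOLD

__all__ = ["SonConfig", "load_config", "save_config"]


@dataclass
class SonConfig:
    oscillator: OscillatorParams = field(default_factory=OscillatorParams)
    excitation: ExcitationParams = field(default_factory=ExcitationParams)
    dt_us: float = DEFAULT_DT_US
    t_max_us: float = DEFAULT_T_MAX_US
    seed: int = 0
    record_stride: int = DEFAULT_RECORD_STRIDE
    stop_os_phases: int = DEFAULT_STOP_OS_PHASES
    rail_V: float = DEFAULT_RAIL_V
    sync_threshold: float = DEFAULT_SYNC_THRESHOLD
    tile_size: int = 32
    threshold_method: str = "otsu"       # "otsu" or "fixed"
    fixed_threshold: float = 128.0
    dark_foreground: bool = True
    smooth_sigma: float = 1.0            # grayscale pre-smoothing, px
    record_voltages: bool = False

    def to_dict(self) -> dict:
        return {
            "oscillator": self.oscillator.to_dict(),
            "excitation": self.excitation.to_dict(),
            "simulation": {
                "dt_us": self.dt_us,
                "t_max_us": self.t_max_us,
                "seed": self.seed,
                "record_stride": self.record_stride,
                "stop_os_phases": self.stop_os_phases,
                "rail_V": self.rail_V,
                "record_voltages": self.record_voltages,
            },
            "labeling": {"sync_threshold": self.sync_threshold},
            "pipeline": {
                "tile_size": self.tile_size,
                "threshold_method": self.threshold_method,
                "fixed_threshold": self.fixed_threshold,
                "dark_foreground": self.dark_foreground,
                "smooth_sigma": self.smooth_sigma,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SonConfig":
        cfg = cls()
        if "oscillator" in d:
            cfg.oscillator = OscillatorParams.from_dict(d["oscillator"])
        if "excitation" in d:
            cfg.excitation = ExcitationParams.from_dict(d["excitation"])
        sim = d.get("simulation", {})
        for key, attr in (("dt_us", "dt_us"), ("t_max_us", "t_max_us"),
                          ("seed", "seed"),
                          ("record_stride", "record_stride"),
                          ("stop_os_phases", "stop_os_phases"),
                          ("rail_V", "rail_V"),
                          ("record_voltages", "record_voltages")):
            if key in sim:
                setattr(cfg, attr, sim[key])
        if "labeling" in d and "sync_threshold" in d["labeling"]:
            cfg.sync_threshold = d["labeling"]["sync_threshold"]
        pl = d.get("pipeline", {})
        for key in ("tile_size", "threshold_method", "fixed_threshold",
                    "dark_foreground", "smooth_sigma"):
            if key in pl:
                setattr(cfg, key, pl[key])
        return cfg


def load_config(path) -> SonConfig:
    with open(path) as fh:
        return SonConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: SonConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
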