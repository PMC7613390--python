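"""Run configuration: YAML schema with defaults and strict key checking."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .phenology import DetectionConfig
from .timeseries import SGConfig

__all__ = ["RunConfig", "validate_config", "ConfigError"]


class ConfigError(ValueError):
    pass


#: full schema with defaults; None means "optional, no default value"
_DEFAULTS = {
    "seed": 0,
    "epoch_year": 2016,
    "years": [2016, 2017],
    "grid_spacing": 10.0,
    "lai_csv": None,          # skip simulation/retrieval, read series from CSV
    "planted_csv": None,      # planted record (required with lai_csv for eval)
    "scenario": {
        "n_parcels": 12,
        "double_frac": 0.34,
        "noise_sd": 0.3,
        "base_lai": 0.2,
        "s2_revisit": 5.0,
        "l8_revisit": 16.0,
        "s2_gap_prob": 0.4,
        "l8_gap_prob": 0.4,
        "jitter": 1.0,
    },
    "retrieval": {
        "enabled": False,
        "n_train": 200,
        "noise_sd": 0.005,
    },
    "detection": {
        "prominence_frac": 0.30,
        "min_separation": 90.0,
        "amplitude_frac": 0.30,
    },
    "sg": {
        "span": 7,
        "degree": 2,
    },
    "mapping": {
        "enabled": True,
        "parcel_size": 4,
        "mask_threshold": 1.0,
    },
}


def _merge(defaults: dict, user: dict, path: str = "") -> tuple[dict, list[str]]:
    out, bad = {}, []
    for key, val in user.items():
        full = f"{path}{key}"
        if key not in defaults:
            bad.append(full)
            continue
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            sub, sub_bad = _merge(defaults[key], val, f"{full}.")
            out[key] = sub
            bad.extend(sub_bad)
        else:
            out[key] = val
    for key, val in defaults.items():
        if key not in out:
            out[key] = dict(val) if isinstance(val, dict) else val
    return out, bad


@dataclass
class RunConfig:
    raw: dict

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def epoch_year(self) -> int:
        return int(self.raw["epoch_year"])

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.raw["years"]]

    @property
    def grid_spacing(self) -> float:
        return float(self.raw["grid_spacing"])

    @property
    def scenario(self) -> dict:
        return self.raw["scenario"]

    @property
    def retrieval(self) -> dict:
        return self.raw["retrieval"]

    @property
    def mapping(self) -> dict:
        return self.raw["mapping"]

    @property
    def lai_csv(self):
        return self.raw["lai_csv"]

    @property
    def planted_csv(self):
        return self.raw["planted_csv"]

    def detection_config(self, method: str = "seasonal") -> DetectionConfig:
        d = self.raw["detection"]
        return DetectionConfig(prominence_frac=float(d["prominence_frac"]),
                               min_separation=float(d["min_separation"]),
                               amplitude_frac=float(d["amplitude_frac"]),
                               method=method)

    def sg_config(self) -> SGConfig:
        return SGConfig(span=int(self.raw["sg"]["span"]),
                        degree=int(self.raw["sg"]["degree"]))


def validate_config(source) -> RunConfig:
    """Load and validate a YAML config (path, mapping, or None for defaults).

    Unknown keys are rejected with an error naming each offending key;
    defaults fill everything omitted; referenced files must exist.
    """
    if source is None:
        user = {}
    elif isinstance(source, dict):
        user = source
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("config root must be a mapping")
    merged, bad = _merge(_DEFAULTS, user)
    if bad:
        raise ConfigError("unknown config keys: " + ", ".join(sorted(bad)))
    cfg = RunConfig(merged)
    for key in ("lai_csv", "planted_csv"):
        val = merged[key]
        if val is not None and not Path(val).exists():
            raise ConfigError(f"{key} points to a missing file: {val}")
    # construct eagerly so threshold errors surface at validation time
    cfg.detection_config()
    cfg.sg_config()
    return cfg
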