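"""Shared run configuration for the command-line workflows.

One YAML file carries the windowing parameters, channel set, detector
thresholds, GRU hyperparameters and evaluation tolerances.  Precedence is
command-line flags > config file > package defaults.  Every command writes
a fully resolved copy of its configuration beside its outputs so a run is
reproducible from that copy alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .features import DEFAULT_CHANNELS, DEFAULT_LABEL_POS, DEFAULT_WINDOW_LEN
from .gru import GruConfig
from .hierarchical import ThresholdConfig
from .records import DEFAULT_SAMPLING_INTERVAL

__all__ = ["RunConfig", "load_config", "resolved_config_yaml", "write_resolved"]


@dataclass
class RunConfig:
    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL
    window_len: int = DEFAULT_WINDOW_LEN
    stride: int = 1
    label_pos: int = DEFAULT_LABEL_POS
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    gru: GruConfig = field(default_factory=GruConfig)
    merge_gap: float = 2.0
    event_tolerance: float = 2.0
    coma_horizon: int = 30
    coma_min_fraction: float = 0.9
    seed: int = 0

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from defaults, an optional YAML file and overrides."""
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    thr = data.pop("thresholds", {})
    gru = data.pop("gru", {})
    for key in ("dense_layers", "dropout_positions"):
        if key in gru:
            gru[key] = tuple(gru[key])
    if "channels" in data:
        data["channels"] = tuple(data["channels"])
    return RunConfig(
        thresholds=ThresholdConfig(**thr), gru=GruConfig(**gru), **data
    )


def resolved_config_yaml(cfg: RunConfig) -> str:
    d = asdict(cfg)
    d["channels"] = list(d["channels"])
    d["gru"]["dense_layers"] = list(d["gru"]["dense_layers"])
    d["gru"]["dropout_positions"] = list(d["gru"]["dropout_positions"])
    return yaml.safe_dump(d, sort_keys=True)


def write_resolved(cfg: RunConfig, out_dir) -> str:
    """Write the resolved config beside outputs; return its content hash."""
    text = resolved_config_yaml(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.yaml").write_text(text)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
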