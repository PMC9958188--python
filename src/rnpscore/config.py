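"""Run configuration: YAML file + CLI overrides, echoed for provenance."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .network.models import NetworkConfig
from .training import TrainingConfig


@dataclass
class RunConfig:
    """Aggregates featurization, network, and training settings.

    Defaults reproduce the published settings: 6 Å interface cutoff,
    L = 128, 32-voxel grids, channels [64,128,256,512,512], learning rate
    1e-4, batch size 1.
    """

    rna_table: str | None = None  # None -> packaged defaults
    protein_table: str | None = None
    cutoff: float = 6.0
    L: int = 128
    grid_size: int = 32
    seed: int = 0
    log_level: str = "INFO"
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        net = raw.pop("network", {})
        trn = raw.pop("training", {})
        cfg = cls(**raw)
        if net:
            cfg.network = NetworkConfig(**{**cfg.network.to_dict(), **net})
        if trn:
            cfg.training = TrainingConfig(**{**asdict(cfg.training), **trn})
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["network"] = self.network.to_dict()
        return d

    def echo(self, out_dir: str | Path) -> Path:
        """Write the effective settings next to the outputs."""
        out = Path(out_dir) / "effective_config.yaml"
        out.parent.mkdir(parents=True, exist_ok=True)
        out.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return out

    def sync(self) -> None:
        """Propagate featurization dims into the network config."""
        if self.network.L != self.L or self.network.grid_size != self.grid_size:
            d = self.network.to_dict()
            d["L"] = self.L
            d["grid_size"] = self.grid_size
            self.network = NetworkConfig(**d)
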