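"""Run configuration: one YAML document covering every parameter group.

``RunConfig`` aggregates the geometry, grid, receptive-field, protocol,
encoder, neuron, background, trainer and decoder parameter groups plus a
global seed and output directory.  Serialization round-trips exactly, and
``config_hash`` covers every parameter so output artifacts can embed the
hash and seed needed to regenerate them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .decoding import DecoderParams
from .encoding import EncoderParams
from .geometry import OutputGrid, SkinGeometry
from .neurons import BackgroundInputParams, NeuronParams
from .skin import IndentationProtocol, ReceptiveFieldModel
from .training import TrainerParams

__all__ = ["RunConfig"]

_GROUPS = {
    "geometry": SkinGeometry,
    "receptive_field": ReceptiveFieldModel,
    "protocol": IndentationProtocol,
    "encoder": EncoderParams,
    "neurons": NeuronParams,
    "background": BackgroundInputParams,
    "trainer": TrainerParams,
    "decoder": DecoderParams,
}


@dataclass
class RunConfig:
    geometry: SkinGeometry = field(default_factory=SkinGeometry)
    receptive_field: ReceptiveFieldModel = field(default_factory=ReceptiveFieldModel)
    protocol: IndentationProtocol = field(default_factory=IndentationProtocol)
    encoder: EncoderParams = field(default_factory=EncoderParams)
    neurons: NeuronParams = field(default_factory=NeuronParams)
    background: BackgroundInputParams = field(default_factory=BackgroundInputParams)
    trainer: TrainerParams = field(default_factory=TrainerParams)
    decoder: DecoderParams = field(default_factory=DecoderParams)
    architecture: str = "SF_DIR"
    grid_n_theta: int = 12
    grid_n_z: int = 9
    n_interneurons: int = 40
    energy_level: float = 0.0
    seed: int = 0
    outdir: str = "out"

    def grid(self) -> OutputGrid:
        return OutputGrid(self.geometry, self.grid_n_theta, self.grid_n_z)

    # --- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            d[f.name] = asdict(v) if f.name in _GROUPS else v
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        for f in fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            if f.name in _GROUPS and isinstance(v, dict):
                v = dict(v)
                for key, val in v.items():
                    if isinstance(val, list):
                        v[key] = tuple(val)
                v = _GROUPS[f.name](**v)
            kwargs[f.name] = v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise ValueError(f"malformed config file {path}")
        try:
            return cls.from_dict(d)
        except (TypeError, ValueError) as e:
            raise ValueError(f"invalid config {path}: {e}") from e

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def metadata(self) -> dict:
        return {"config_hash": self.config_hash(), "seed": self.seed}
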