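"""Pipeline configuration: a YAML-round-trippable bundle of all knobs."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigurationError
from .spine_sim import Alteration, ExcitationConfig


@dataclass
class PipelineConfig:
    """Every tunable of the simulate/analyze/compare pipeline.

    Sections mirror the processing stages; ``model`` overrides entries of the
    default spine model, ``alteration`` describes the structural change given
    to one twin of each discordant pair.
    """

    excitation: dict = field(default_factory=dict)       # ExcitationConfig overrides
    model: dict = field(default_factory=dict)            # spine-model overrides
    alteration: dict = field(default_factory=dict)       # Alteration overrides
    n_pairs_concordant: int = 5
    n_pairs_discordant: int = 5
    variability: float = 0.02
    between_pair_variability: float = 0.10
    band: tuple[float, float] = (1.0, 2000.0)
    window: str = "boxcar"
    kernel_bins: int = 5
    frf_convention: str = "power"
    qc_threshold: float = 0.5
    method: str = "paired-t"
    alpha: float = 0.05
    seed: int = 0

    def excitation_config(self) -> ExcitationConfig:
        return ExcitationConfig(**self.excitation)

    def alteration_config(self) -> Alteration:
        return Alteration(**self.alteration)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "band" in d:
            d["band"] = tuple(d["band"])
        return cls(**d)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Short stable digest identifying this configuration."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
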