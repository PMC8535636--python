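"""Single validated configuration record for end-to-end runs.

One YAML file holds every hyperparameter and under-specified choice of an
experiment — generator, degradation, split, the three subnet configs, the
regime and the seed — so a run is fully reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .case import ValidationError
from .synthetic import BlurSpec, SynthSpec


@dataclass
class PipelineConfig:
    """Everything an end-to-end cascade experiment depends on."""

    mode: str = "common"  # or "mtl_if"
    seed: int = 0
    split_ratio: float = 0.8
    out_dir: str = "runs"
    synth: dict = field(default_factory=dict)
    blur: dict = field(default_factory=lambda: {"sigma": [1.0, 3.0]})
    iqa: dict = field(default_factory=dict)
    deblur: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=dict)

    def validate(self) -> "PipelineConfig":
        if self.mode not in ("common", "mtl_if"):
            raise ValidationError(f"mode must be 'common' or 'mtl_if', got {self.mode!r}")
        if not 0 < self.split_ratio < 1:
            raise ValidationError(f"split_ratio must be in (0, 1), got {self.split_ratio}")
        SynthSpec(**{**self.synth, "seed": self.seed}).validate()
        sigma = self.blur.get("sigma", 2.0)
        s = sigma[0] if isinstance(sigma, (list, tuple)) else sigma
        BlurSpec(sigma=float(s)).validate()
        return self

    @property
    def deblur_in_channels(self) -> int:
        """The guided regime concatenates one attention channel."""
        return 8 if self.mode == "mtl_if" else 7

    def synth_spec(self) -> SynthSpec:
        return SynthSpec(**{**self.synth, "seed": self.seed})

    def blur_sigma(self):
        sigma = self.blur.get("sigma", 2.0)
        return tuple(sigma) if isinstance(sigma, (list, tuple)) else float(sigma)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path


def load_config(path: str | Path) -> PipelineConfig:
    """Read and validate a YAML config file."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw).validate()
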