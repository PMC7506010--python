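"""Run configuration: YAML-loadable parameters and provenance.

Defaults equal the published pipeline constants (8/0.25 Hz 6th-order
Butterworth cascade, 16 entropy bins, 100 task trees / 50 aggregator
trees, severity class edges 30/38/47/56, LOSO cross-validation); any
override is recorded in the provenance blob every run writes.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .models import ModelConfig
from .simulate import SimConfig

__all__ = ["RunConfig", "load_config", "provenance"]


@dataclass
class RunConfig:
    seed: int = 0
    lowpass_hz: float = 8.0
    highpass_hz: float = 0.25
    filter_order: int = 6
    entropy_bins: int = 16
    cv: str = "loso"  # "loso" or "kfold:<k>"
    sim: SimConfig = field(default_factory=SimConfig)
    model: ModelConfig = field(default_factory=ModelConfig)

    def overrides(self) -> dict:
        """Fields that differ from the defaults."""
        ref = RunConfig()
        out = {}
        for f in fields(self):
            a, b = getattr(self, f.name), getattr(ref, f.name)
            if isinstance(a, (SimConfig, ModelConfig)):
                sub = {
                    g.name: getattr(a, g.name)
                    for g in fields(a)
                    if getattr(a, g.name) != getattr(b, g.name)
                }
                if sub:
                    out[f.name] = sub
            elif a != b:
                out[f.name] = a
        return out

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    The YAML may contain top-level keys plus ``sim:`` and ``model:``
    sections mirroring the dataclass fields.
    """
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update(overrides)
    sim = SimConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in (data.pop("sim", {}) or {}).items()
    })
    model = ModelConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in (data.pop("model", {}) or {}).items()
    })
    cfg = RunConfig(sim=sim, model=model, **data)
    if "seed" in overrides or "seed" in data:
        cfg.sim.seed = cfg.seed
    return cfg


def provenance(config: RunConfig, command: str) -> dict:
    """Provenance blob written next to every command's artifacts."""
    import numpy
    import scipy
    import sklearn

    from . import __version__

    return {
        "command": command,
        "seed": config.seed,
        "config_hash": config.digest(),
        "overrides": config.overrides(),
        "versions": {
            "armscore": __version__,
            "python": platform.python_version(),
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "sklearn": sklearn.__version__,
        },
    }
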