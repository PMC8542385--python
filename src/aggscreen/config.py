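"""Run configuration: YAML loading, strict key validation, provenance echo.

Precedence is CLI flags > config file > built-in defaults. Every analysis
run echoes its fully resolved configuration (plus the package version) into
the output directory so results stay reproducible.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import yaml

from .detection import DEFAULT_QC_THRESHOLD, AggregateParams
from .fragments import FragmentParams
from .segmentation import SegmentationParams
from .synthetic import GenerationConfig

__all__ = ["RunConfig"]


def _build(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) in config section '{section}': {sorted(unknown)}")
    return cls(**data)


@dataclass
class RunConfig:
    """Resolved configuration for one run; all fields have defaults."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    aggregates: AggregateParams = field(default_factory=AggregateParams)
    fragments: FragmentParams = field(default_factory=FragmentParams)
    generation: GenerationConfig = field(default_factory=GenerationConfig)
    qc_threshold: float = DEFAULT_QC_THRESHOLD
    screen_cutoff: float = 0.25
    channel_map: dict = field(default_factory=lambda: {"nuclei": 0, "gfp": 1})
    seed: int = 0

    _SECTIONS = {
        "segmentation": SegmentationParams,
        "aggregates": AggregateParams,
        "fragments": FragmentParams,
        "generation": GenerationConfig,
    }
    _SCALARS = ("qc_threshold", "screen_cutoff", "channel_map", "seed")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - set(cls._SECTIONS) - set(cls._SCALARS)
        if unknown:
            raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
        kwargs = {}
        for name, klass in cls._SECTIONS.items():
            if name in data:
                kwargs[name] = _build(klass, data[name] or {}, name)
        for name in cls._SCALARS:
            if name in data:
                kwargs[name] = data[name]
        return cls(**kwargs)

    def with_overrides(self, **sections) -> "RunConfig":
        """Return a copy with dataclass sections replaced field-wise."""
        out = dataclasses.replace(self)
        for name, override in sections.items():
            if not override:
                continue
            if name in self._SECTIONS:
                current = getattr(out, name)
                out = dataclasses.replace(out, **{name: dataclasses.replace(current, **override)})
            else:
                out = dataclasses.replace(out, **{name: override})
        return out

    def to_dict(self) -> dict:
        d = {name: dataclasses.asdict(getattr(self, name)) for name in self._SECTIONS}
        for name in self._SCALARS:
            d[name] = getattr(self, name)
        return d

    def echo(self, out_dir: str) -> str:
        """Write the resolved config + package version into ``out_dir``."""
        from . import __version__

        os.makedirs(out_dir, exist_ok=True)
        path = os.path.join(out_dir, "resolved_config.yaml")
        payload = dict(self.to_dict(), aggscreen_version=__version__)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
        return path
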