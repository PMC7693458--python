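"""Run configuration for the end-to-end analysis pipeline."""

from __future__ import annotations

import os
from dataclasses import dataclass, field, fields

import yaml

from .vision import DEFAULT_LAMBDA_MAX


class ConfigError(ValueError):
    """Invalid run configuration; ``errors`` lists every violated field."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


@dataclass
class RunConfig:
    """All knobs of a pipeline run, with the analysis defaults.

    Exactly one input source must be given: ``manifest`` (a CSV mapping
    spectrum files to plant/structure/position) or ``generator`` (keyword
    overrides for the synthetic generator; ``{}`` uses its defaults).
    """

    manifest: str | None = None
    generator: dict | None = None
    dialect: str = "fraction"
    lambda_max: tuple = DEFAULT_LAMBDA_MAX
    illuminant: str = "D65"
    background: str = "green_leaf"
    grid: tuple = (300.0, 700.0, 1.0)
    locus_step: float = 1.0
    rotation_deg: float = 0.0
    alpha: float = 0.05
    circular_alpha: float = 0.001
    n_perm: int = 10000
    n_boot: int = 1000
    seed: int = 0
    out_dir: str = "florahex_out"

    def validate(self) -> "RunConfig":
        errors = []
        if (self.manifest is None) == (self.generator is None):
            errors.append("exactly one of 'manifest' and 'generator' must be given")
        if self.manifest is not None and not os.path.exists(self.manifest):
            errors.append(f"manifest: file not found: {self.manifest}")
        for name in ("alpha", "circular_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                errors.append(f"{name}: must be in (0, 1), got {v}")
        if self.n_perm < 100:
            errors.append(f"n_perm: must be >= 100, got {self.n_perm}")
        if self.n_boot < 1:
            errors.append(f"n_boot: must be >= 1, got {self.n_boot}")
        if len(self.lambda_max) != 3 or sorted(self.lambda_max) != list(self.lambda_max):
            errors.append(f"lambda_max: need an increasing UV/blue/green triple, got {self.lambda_max}")
        lo, hi, step = (self.grid + (1.0,))[:3] if len(self.grid) >= 2 else (0, 0, 0)
        if not (lo <= 300.0 and hi >= 700.0 and step > 0):
            errors.append(f"grid: (lo, hi, step) must span [300, 700] nm, got {self.grid}")
        if self.dialect not in ("fraction", "percent"):
            errors.append(f"dialect: 'fraction' or 'percent', got {self.dialect!r}")
        if errors:
            raise ConfigError(errors)
        return self


def validate_config(path) -> RunConfig:
    """Parse a YAML config file into a validated :class:`RunConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError([f"unknown field(s): {sorted(unknown)}"])
    if "lambda_max" in raw:
        raw["lambda_max"] = tuple(raw["lambda_max"])
    if "grid" in raw:
        raw["grid"] = tuple(raw["grid"])
    return RunConfig(**raw).validate()
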