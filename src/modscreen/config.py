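"""Run configuration: a single YAML file with per-stage sections.

Unknown top-level keys are rejected so typos fail fast. Every output file
the pipeline writes carries the seed and a short hash of the effective
configuration in a header line, making runs attributable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .errors import ConfigError
from .filtering import FilterConfig
from .fixture import fixture_primary_allele
from .io import PrimaryAllele
from .simulate import MutagenSpectrum, ScreenPlan, default_spectrum

_SECTIONS = (
    "seed",
    "outdir",
    "paths",
    "simulate",
    "filter",
    "spectra",
    "revertant",
    "phenotype",
    "cost",
    "primary",
)


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "modscreen_out"
    paths: dict[str, str] = field(default_factory=dict)
    simulate: dict[str, Any] = field(default_factory=dict)
    filter: dict[str, Any] = field(default_factory=dict)
    spectra: dict[str, dict[str, float]] = field(default_factory=dict)
    revertant: dict[str, Any] = field(default_factory=dict)
    phenotype: dict[str, Any] = field(default_factory=dict)
    cost: dict[str, Any] = field(default_factory=dict)
    primary: dict[str, Any] = field(default_factory=dict)

    # -- derived objects ----------------------------------------------------

    def screen_plan(self) -> ScreenPlan:
        try:
            return ScreenPlan(seed=self.seed, **self.simulate)
        except TypeError as exc:
            raise ConfigError(f"invalid simulate section: {exc}") from None

    def filter_config(self) -> FilterConfig:
        try:
            return FilterConfig(**self.filter)
        except TypeError as exc:
            raise ConfigError(f"invalid filter section: {exc}") from None

    def spectrum(self, mutagen: str) -> MutagenSpectrum:
        if mutagen in self.spectra:
            return MutagenSpectrum(dict(self.spectra[mutagen]))
        return default_spectrum(mutagen)

    def primary_allele(self) -> PrimaryAllele:
        if not self.primary:
            return fixture_primary_allele()
        try:
            return PrimaryAllele(**self.primary)
        except TypeError as exc:
            raise ConfigError(f"invalid primary section: {exc}") from None

    def hash(self) -> str:
        # outdir and input locations are excluded: the hash identifies the
        # scientific parameters, not where files happen to live
        sections = [s for s in _SECTIONS if s not in ("outdir", "paths")]
        payload = json.dumps(
            {s: getattr(self, s) for s in sections}, sort_keys=True, default=str
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def header_comment(self) -> str:
        return f"modscreen seed={self.seed} config={self.hash()}"


def load_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> RunConfig:
    """Load a YAML config file; missing file fields fall back to defaults."""
    data: dict[str, Any] = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        loaded = yaml.safe_load(p.read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{p}: config must be a mapping")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
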