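"""YAML pipeline configuration with validation and default filling.

A config file may name a built-in scenario and/or override any parameter
block; unknown keys are rejected with the offending key named, and every
invariant of the underlying parameter dataclasses is enforced at load time.
The fully resolved config (defaults included) is echoed into the run report
for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .diffusion import AnalysisParams
from .localize import WaveletParams
from .puncta import PunctaParams
from .simulate import SCENARIOS, Geometry, OpticsConfig, SimulationConfig, _default_geometry
from .srmap import MapParams
from .track import TrackingParams

__all__ = ["PipelineConfig", "load_config"]


def _build(cls, block: dict, name: str):
    """Instantiate a parameter dataclass from a mapping, rejecting unknown keys."""
    allowed = {f.name for f in fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in config block '{name}'")
    coerced = {}
    for f in fields(cls):
        if f.name in block:
            v = block[f.name]
            coerced[f.name] = tuple(map(tuple, v)) if isinstance(v, list) and v and isinstance(v[0], list) else (tuple(v) if isinstance(v, list) else v)
    return cls(**coerced)


@dataclass
class PipelineConfig:
    scenario: str = "DIV8"
    mode: str = "tables"             # "tables" (degrade) or "movie" (render+detect)
    seed: int = 0
    output_dir: str = "synaptrack_out"
    simulation: SimulationConfig = field(default_factory=lambda: SCENARIOS["DIV8"])
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    wavelet: WaveletParams = field(default_factory=WaveletParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    map: MapParams = field(default_factory=MapParams)
    puncta: PunctaParams = field(default_factory=PunctaParams)
    geometry: Geometry = field(default_factory=_default_geometry)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


_BLOCKS = {
    "simulation": SimulationConfig,
    "optics": OpticsConfig,
    "wavelet": WaveletParams,
    "tracking": TrackingParams,
    "analysis": AnalysisParams,
    "map": MapParams,
    "puncta": PunctaParams,
}
_SCALARS = {"scenario", "mode", "seed", "output_dir"}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load and validate a pipeline config; an empty file yields all defaults."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
    if overrides:
        raw = {**raw, **{k: v for k, v in overrides.items() if v is not None}}

    unknown = set(raw) - _SCALARS - set(_BLOCKS) - {"geometry"}
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")

    scenario = raw.get("scenario", "DIV8")
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}")
    mode = raw.get("mode", "tables")
    if mode not in {"tables", "movie"}:
        raise ValueError(f"mode must be 'tables' or 'movie', got {mode!r}")

    sim_block = dict(raw.get("simulation", {}))
    base = dataclasses.asdict(SCENARIOS[scenario])
    base.update(sim_block)
    simulation = _build(SimulationConfig, base, "simulation")

    if "geometry" in raw:
        g = raw["geometry"]
        geometry = Geometry(
            dendrite_rect=tuple(g.get("dendrite_rect", (0.0, 0.0, 40.0, 3.2))),
            synapses=tuple(tuple(s) for s in g.get("synapses", ())),
        )
    else:
        geometry = _default_geometry()

    return PipelineConfig(
        scenario=scenario,
        mode=mode,
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "synaptrack_out")),
        simulation=simulation,
        geometry=geometry,
        **{name: _build(cls, dict(raw.get(name, {})), name) for name, cls in _BLOCKS.items() if name != "simulation"},
    )
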