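"""YAML configuration loading for simulations.

Schema (all keys optional; defaults in parentheses)::

    geometry: disc | spheroid        (disc)
    radius: 100.0                    # um
    horizon: 4640.0                  # min
    record_interval: 10.0
    alive_includes_dying: false
    treatment:
      period: 150.0                  # min
      duration: 20.0                 # min
      concentration: 0.3             # ng/L
    variability:
      sigma: 0.0
      floor: 0.01
    seeds: [0, 1, 2]
    receptor:
      k_bind: 2.0                    # 1/((ng/L) min)
      k_endo: 0.05                   # 1/min
      k_recycle: 0.2                 # 1/min
      R_total: 1.0
      activation_threshold: 0.5
    network: path/to/file.bnet       (shipped surrogate)
    steps:
      diffusion: 0.1                 # min
      mechanics: 0.5
      intracellular: 6.0
      receptor_substep: 0.1
    microenvironment:
      diffusion_coefficient: 1200.0  # um^2/min
      decay_rate: 0.0275             # 1/min
      voxel_size: 20.0               # um
      margin: 100.0                  # um
      supply: boundary | uniform     (boundary)
      uptake_enabled: true
      uptake_scale: 200.0
    population:
      cell_volume: 2494.0
      spacing_2d: 0.95
      spacing_3d: 1.0
      apoptosis_duration: 516.0
      necrosis_duration: 1440.0
      doubling_time: 1320.0
      mechanics_enabled: true
      repulsion: 10.0
"""

from __future__ import annotations

import yaml

from .receptor import ReceptorParams
from .simulation import (MicroenvConfig, PopulationConfig, SimulationConfig,
                         TimeStepConfig)
from .treatment import PulseSchedule, VariabilityConfig

__all__ = ["load_config", "config_from_dict"]

_STEP_KEYS = {"diffusion", "mechanics", "intracellular", "receptor_substep"}


def _sub(cls, data: dict | None, rename: dict | None = None):
    data = dict(data or {})
    for old, new in (rename or {}).items():
        if old in data:
            data[new] = data.pop(old)
    return cls(**data)


def config_from_dict(data: dict) -> SimulationConfig:
    data = dict(data or {})
    kwargs = {}
    for key in ("geometry", "radius", "horizon", "record_interval",
                "alive_includes_dying"):
        if key in data:
            kwargs[key] = data[key]
    if "treatment" in data:
        kwargs["schedule"] = _sub(PulseSchedule, data["treatment"])
    if "variability" in data:
        kwargs["variability"] = _sub(VariabilityConfig, data["variability"])
    if "seeds" in data:
        kwargs["seeds"] = tuple(int(s) for s in data["seeds"])
    if "receptor" in data:
        kwargs["receptor"] = _sub(ReceptorParams, data["receptor"])
    if "network" in data:
        kwargs["network_path"] = data["network"]
    if "steps" in data:
        unknown = set(data["steps"]) - _STEP_KEYS
        if unknown:
            raise ValueError(f"unknown steps keys: {sorted(unknown)}")
        kwargs["steps"] = _sub(TimeStepConfig, data["steps"])
    if "microenvironment" in data:
        kwargs["microenv"] = _sub(MicroenvConfig, data["microenvironment"])
    if "population" in data:
        kwargs["population"] = _sub(PopulationConfig, data["population"])
    return SimulationConfig(**kwargs)


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})
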