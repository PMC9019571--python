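"""Pulsed-TNF treatment schedules, dose accounting and per-cell variability.

A treatment is the 3-vector (pulse period, pulse duration, TNF concentration);
the search box used throughout is period 5-800 min, duration 5-200 min,
concentration 0.001-1 ng/L.  Population heterogeneity is modelled by sampling
each cell's three receptor kinetic rates from a normal distribution centred on
the default value with a *relative* standard deviation sigma in [0, 1],
truncated below (by resampling) at a small fraction of the mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PulseSchedule",
    "VariabilityConfig",
    "pulse_active",
    "total_tnf",
    "sample_cell_params",
    "sample_param_arrays",
    "SEARCH_BOX",
]

#: default search box: ((period), (duration), (concentration)) bounds
SEARCH_BOX = ((5.0, 800.0), (5.0, 200.0), (0.001, 1.0))


@dataclass(frozen=True)
class PulseSchedule:
    """Periodic TNF supply: pulses of `duration` min every `period` min,
    starting at t=0, at `concentration` ng/L."""

    period: float
    duration: float
    concentration: float

    def __post_init__(self):
        if self.period <= 0 or self.duration <= 0:
            raise ValueError("period and duration must be positive")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.duration > self.period:
            raise ValueError("duration must not exceed period")
        box = SEARCH_BOX
        if not (box[0][0] <= self.period <= box[0][1]
                and box[1][0] <= self.duration <= box[1][1]
                and box[2][0] <= self.concentration <= box[2][1]):
            warnings.warn(
                f"schedule {self} lies outside the standard search box "
                f"{box}", stacklevel=2)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.period, self.duration, self.concentration)


@dataclass(frozen=True)
class VariabilityConfig:
    """Relative-sd heterogeneity of the receptor kinetic rates.

    sigma=0 is a homogeneous (clonal) population; sigma=1 makes the rates
    almost uniformly spread.  Draws below floor*mean are resampled (not
    clipped) so rates stay positive without a point mass at the floor.
    """

    sigma: float = 0.0
    floor: float = 0.01

    def __post_init__(self):
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError("sigma must be in [0, 1]")
        if not 0.0 < self.floor < 1.0:
            raise ValueError("floor must be a fraction of the mean in (0, 1)")


def pulse_active(schedule: PulseSchedule, t: float) -> bool:
    """True iff a pulse is on at time t (pulses start at t=0)."""
    if t < 0:
        raise ValueError("t must be non-negative")
    return (t % schedule.period) < schedule.duration


def total_tnf(schedule: PulseSchedule, horizon: float) -> float:
    """Total supplied dose duration*concentration*n over the horizon (ng*min/L).

    n is the number of whole pulse periods, floor(horizon/period); a final
    partial pulse is excluded.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    n = np.floor(horizon / schedule.period)
    return float(schedule.duration * schedule.concentration * n)


def _truncated_normal(rng: np.random.Generator, mean: float, sigma: float,
                      floor: float, size: int) -> np.ndarray:
    """Normal(mean, sigma*mean) resampled until every draw exceeds floor*mean."""
    if sigma == 0.0:
        return np.full(size, mean)
    out = rng.normal(mean, sigma * mean, size)
    lo = floor * mean
    bad = out < lo
    while np.any(bad):
        out[bad] = rng.normal(mean, sigma * mean, int(bad.sum()))
        bad = out < lo
    return out


def sample_cell_params(base, cfg: VariabilityConfig,
                       rng: np.random.Generator):
    """One cell's ReceptorParams with k_bind/k_endo/k_recycle perturbed.

    R_total and the activation threshold are never varied.  sigma=0 returns
    the base parameters exactly.
    """
    if cfg.sigma == 0.0:
        return base
    kb, ke, kr = (
        _truncated_normal(rng, base.k_bind, cfg.sigma, cfg.floor, 1)[0],
        _truncated_normal(rng, base.k_endo, cfg.sigma, cfg.floor, 1)[0],
        _truncated_normal(rng, base.k_recycle, cfg.sigma, cfg.floor, 1)[0],
    )
    return replace(base, k_bind=kb, k_endo=ke, k_recycle=kr)


def sample_param_arrays(base, cfg: VariabilityConfig, n: int,
                        rng: np.random.Generator):
    """Vectorised per-cell (k_bind, k_endo, k_recycle) arrays for n cells."""
    kb = _truncated_normal(rng, base.k_bind, cfg.sigma, cfg.floor, n)
    ke = _truncated_normal(rng, base.k_endo, cfg.sigma, cfg.floor, n)
    kr = _truncated_normal(rng, base.k_recycle, cfg.sigma, cfg.floor, n)
    return kb, ke, kr
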