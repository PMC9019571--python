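"""Orchestration of one in-silico treatment experiment.

A simulation couples four submodels on a fixed time-step hierarchy:

* microenvironment transport (``dt_diffusion``): implicit diffusion + decay
  of the TNF field with pulsed boundary (or uniform) supply;
* per-cell receptor kinetics (``dt_intracellular`` windows, RK4 substeps):
  each alive cell integrates its three-pool receptor model at the local TNF
  concentration read at the beginning of the window, and the internalized
  ligand is withdrawn from the field;
* the cell-fate Boolean network: the receptor transfer function clamps the
  network's TNF input, then each cell's network advances one window of CTMC
  time and the fate readout maps to phenotype (divide / die / idle);
* population mechanics (``dt_mechanics``): overdamped repulsion relaxation.

Everything is deterministic given (config, seed).  A treatment is scored by
the mean final alive count over replicate seeds, and called *effective* when
the final alive count is below 1% of the initial count in every replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels, microenv
from .boolnet import BooleanNetwork, load_network
from .population import (Population, advance_cycle, initialize_disc,
                         initialize_spheroid, mechanics_step,
                         update_death, update_phenotype)
from .receptor import ReceptorParams
from .treatment import PulseSchedule, VariabilityConfig, total_tnf

__all__ = [
    "TimeStepConfig",
    "MicroenvConfig",
    "PopulationConfig",
    "SimulationConfig",
    "TimeCourse",
    "run_simulation",
    "score_treatment",
    "is_effective",
]


@dataclass(frozen=True)
class TimeStepConfig:
    """Time-step hierarchy (minutes)."""

    diffusion: float = 0.1
    mechanics: float = 0.5
    intracellular: float = 6.0
    receptor_substep: float = 0.1


@dataclass(frozen=True)
class MicroenvConfig:
    diffusion_coefficient: float = 1200.0   # um^2/min
    decay_rate: float = 0.0275              # 1/min
    voxel_size: float = 20.0                # um
    margin: float = 100.0                   # um beyond the cell arrangement
    supply: str = "boundary"                # boundary | uniform
    uptake_enabled: bool = True
    uptake_scale: float = 200.0             # ng*um^3/L per receptor unit
    oxygen_enabled: bool = False


@dataclass(frozen=True)
class PopulationConfig:
    cell_volume: float = 2494.0
    spacing_2d: float = 0.95
    spacing_3d: float = 1.0
    apoptosis_duration: float = 516.0
    necrosis_duration: float = 1440.0
    doubling_time: float = 1320.0
    mechanics_enabled: bool = True
    repulsion: float = 10.0


@dataclass(frozen=True)
class SimulationConfig:
    """Full experiment description; see the module docstring for the loop."""

    geometry: str = "disc"                  # disc | spheroid
    radius: float = 100.0
    horizon: float = 4640.0
    record_interval: float = 10.0
    schedule: PulseSchedule = field(
        default_factory=lambda: PulseSchedule(150.0, 20.0, 0.3))
    variability: VariabilityConfig = field(default_factory=VariabilityConfig)
    seeds: tuple[int, ...] = (0, 1, 2)
    receptor: ReceptorParams = field(default_factory=ReceptorParams)
    network_path: str | None = None
    steps: TimeStepConfig = field(default_factory=TimeStepConfig)
    microenv: MicroenvConfig = field(default_factory=MicroenvConfig)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    alive_includes_dying: bool = False

    def with_schedule(self, schedule: PulseSchedule) -> "SimulationConfig":
        return replace(self, schedule=schedule)


@dataclass
class TimeCourse:
    """Recorded population and receptor trajectories of one simulation."""

    t: np.ndarray
    alive: np.ndarray
    apoptotic: np.ndarray
    necrotic: np.ndarray
    mean_re: np.ndarray
    mean_re_star: np.ndarray
    mean_ri_star: np.ndarray
    frac_input_on: np.ndarray
    pulse_on: np.ndarray
    initial_alive: int
    final_alive: int
    ledger: dict
    population: Population
    field: "microenv.ScalarField"

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "t": self.t, "alive": self.alive, "apoptotic": self.apoptotic,
            "necrotic": self.necrotic, "mean_Re": self.mean_re,
            "mean_Re_star": self.mean_re_star,
            "mean_Ri_star": self.mean_ri_star,
            "frac_input_on": self.frac_input_on, "pulse_on": self.pulse_on,
        })

    def summary(self, config: SimulationConfig) -> dict:
        return {
            "initial_alive": self.initial_alive,
            "final_alive": self.final_alive,
            "total_tnf": total_tnf(config.schedule, config.horizon),
            "ledger": self.ledger,
        }


def _make_population(config: SimulationConfig, seed: int,
                     net: BooleanNetwork) -> Population:
    if config.geometry == "disc":
        pop = initialize_disc(config.radius, config.population.spacing_2d,
                              config.population.cell_volume)
    elif config.geometry == "spheroid":
        pop = initialize_spheroid(config.radius,
                                  config.population.spacing_3d,
                                  config.population.cell_volume)
    else:
        raise ValueError(f"unknown geometry '{config.geometry}'")
    pop.attach_intracellular(net, config.receptor, config.variability,
                             seed=seed)
    return pop


def run_simulation(config: SimulationConfig, seed: int) -> TimeCourse:
    """Run one replicate; deterministic given (config, seed)."""
    net = load_network(config.network_path)
    tnf_inputs = [i for i, name in enumerate(net.names)
                  if net.is_input[i] and name.upper() == "TNF"]
    if not tnf_inputs:
        raise ValueError("network declares no clamped input named TNF")
    tnf_node = tnf_inputs[0]

    pop = _make_population(config, seed, net)
    me = config.microenv
    fld = microenv.ScalarField(
        "tnf", pop.dims, me.voxel_size, config.radius + me.margin,
        me.diffusion_coefficient, me.decay_rate)
    supply = (microenv.apply_boundary_pulse if me.supply == "boundary"
              else microenv.apply_uniform_pulse)
    oxygen = None
    if me.oxygen_enabled:
        # non-limiting oxygen: transported but not coupled to any phenotype
        oxygen = microenv.ScalarField(
            "oxygen", pop.dims, me.voxel_size, config.radius + me.margin,
            100_000.0, 0.0)
        oxygen.concentrations[:] = 38.0  # mmHg, well-oxygenated
    # safe interior for voxel lookups after mechanics drift
    pos_lim = -fld.origin - 0.51 * me.voxel_size

    st = config.steps
    thr = config.receptor.activation_threshold * config.receptor.R_total
    b_time = config.population.doubling_time

    rec_t, rec_alive, rec_apo, rec_nec = [], [], [], []
    rec_re, rec_res, rec_ris, rec_in, rec_pulse = [], [], [], [], []

    def record(t):
        alive = pop.alive
        n = int(alive.sum())
        counts = pop.counts()
        rec_t.append(t)
        rec_alive.append(n)
        rec_apo.append(counts["apoptotic"])
        rec_nec.append(counts["necrotic"])
        if n:
            rec_re.append(float(pop.re[alive].mean()))
            rec_res.append(float(pop.res[alive].mean()))
            rec_ris.append(float(pop.ris[alive].mean()))
            rec_in.append(float((pop.res[alive] >= thr).mean()))
        else:
            rec_re.append(np.nan)
            rec_res.append(np.nan)
            rec_ris.append(np.nan)
            rec_in.append(0.0)
        from .treatment import pulse_active
        rec_pulse.append(pulse_active(config.schedule, min(t,
                                                           config.horizon)))

    initial_alive = pop.alive_count()
    record(0.0)
    next_record = config.record_interval

    t = 0.0
    while t < config.horizon - 1e-9:
        try:
            t = _advance_window(config, pop, fld, net, supply, oxygen,
                                tnf_node, thr, b_time, t)
        except Exception as exc:  # annotate submodule aborts with context
            exc.add_note(f"while advancing the window starting at t={t:g} "
                         f"min (seed {seed})")
            raise
        if t >= next_record - 1e-9 or t >= config.horizon - 1e-9:
            record(t)
            while next_record <= t + 1e-9:
                next_record += config.record_interval

    return TimeCourse(
        t=np.array(rec_t), alive=np.array(rec_alive),
        apoptotic=np.array(rec_apo), necrotic=np.array(rec_nec),
        mean_re=np.array(rec_re), mean_re_star=np.array(rec_res),
        mean_ri_star=np.array(rec_ris), frac_input_on=np.array(rec_in),
        pulse_on=np.array(rec_pulse, dtype=bool),
        initial_alive=initial_alive,
        final_alive=_alive_for_scoring(pop, config),
        ledger=fld.ledger(), population=pop, field=fld)


def _advance_window(config, pop, fld, net, supply, oxygen, tnf_node, thr,
                    b_time, t):
    """One dt_intracellular window of the coupled model; returns the new t."""
    st = config.steps
    me = config.microenv
    pos_lim = -fld.origin - 0.51 * me.voxel_size
    win = min(st.intracellular, config.horizon - t)

    # local TNF at the beginning of the window
    alive_idx = np.nonzero(pop.alive)[0]
    if len(alive_idx):
        vox = np.floor(
            (pop.positions[alive_idx, :pop.dims] - fld.origin)
            / fld.voxel_size).astype(np.int64)
        np.clip(vox, 0, fld.shape[0] - 1, out=vox)
        local_tnf = fld.concentrations[tuple(vox.T)]
    else:
        vox = np.zeros((0, pop.dims), dtype=np.int64)
        local_tnf = np.zeros(0)

    # transport substeps with pulsed supply
    nsub = max(1, int(np.ceil(win / st.diffusion)))
    sub = win / nsub
    for k in range(nsub):
        supply(fld, config.schedule, t + k * sub)
        microenv.diffuse_decay_step(fld, sub)
    if oxygen is not None:
        microenv.diffuse_decay_step(oxygen, win)

    if len(alive_idx):
        # receptor kinetics and uptake
        re = pop.re[alive_idx]
        res = pop.res[alive_idx]
        ris = pop.ris[alive_idx]
        consumed = _kernels.receptor_rk4(
            re, res, ris, pop.kb[alive_idx], pop.ke[alive_idx],
            pop.kr[alive_idx], local_tnf, win, st.receptor_substep)
        pop.re[alive_idx] = re
        pop.res[alive_idx] = res
        pop.ris[alive_idx] = ris
        if me.uptake_enabled:
            microenv.consume_at_voxels(fld, vox, consumed * me.uptake_scale)

        # transfer function clamps the network input, then CTMC window
        pop.net_values[alive_idx, tnf_node] = (res >= thr).astype(np.uint8)
        vals = pop.net_values[alive_idx]
        counters = pop.ctmc_counters[alive_idx]
        _kernels.gillespie_window(
            vals, net.is_input, net.rate_up, net.rate_down, net.code,
            net.arg, net.starts, net.ends, win,
            pop.ctmc_keys[alive_idx], counters)
        pop.net_values[alive_idx] = vals
        pop.ctmc_counters[alive_idx] = counters

        update_phenotype(pop)
        advance_cycle(pop, win, b_time)

    update_death(pop, win)

    if config.population.mechanics_enabled and len(pop) > 1:
        nmech = max(1, int(round(win / st.mechanics)))
        mechanics_step(pop, win / nmech, config.population.repulsion, nmech)
        np.clip(pop.positions[:, :pop.dims], -pos_lim, pos_lim,
                out=pop.positions[:, :pop.dims])

    return t + win


def _alive_for_scoring(pop: Population, config: SimulationConfig) -> int:
    if config.alive_includes_dying:
        c = pop.counts()
        return c["alive"] + c["apoptotic"] + c["necrotic"]
    return pop.alive_count()


def score_treatment(config: SimulationConfig, schedule: PulseSchedule,
                    seeds=None) -> tuple[float, list[int]]:
    """Mean final alive count over replicate seeds (the treatment fitness)."""
    seeds = list(config.seeds if seeds is None else seeds)
    if not seeds:
        raise ValueError("at least one replicate seed is required")
    finals = [run_simulation(config.with_schedule(schedule), s).final_alive
              for s in seeds]
    return float(np.mean(finals)), finals


def is_effective(finals, initial: int, threshold: float = 0.01) -> bool:
    """True iff final/initial < threshold in every replicate."""
    if initial <= 0:
        raise ValueError("initial count must be positive")
    return all(f / initial < threshold for f in finals)
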