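"""Cell agents: lattice placement, live cycle, death models, mechanics.

Cells are stored structure-of-arrays in a :class:`Population` for speed; a
:class:`Cell` view exposes one agent's fields.  Initial geometries follow the
packed-lattice conventions of PhysiCell-style simulators:

* 2-D disc: hexagonal lattice with nearest-neighbour spacing
  ``spacing_factor * cell diameter`` (default factor 0.95, frozen by
  calibration against the published initial counts: 151 cells at r=100 um,
  37 at r=50 um, 1,069 at r=275 um, 3,559 at r=500 um).
* 3-D spheroid: layered lattice with x/z spacing ``r*sqrt(3)`` and y spacing
  ``2r`` with parity offsets (r = spacing_factor * cell radius, default
  factor 1.0), giving 1,173 cells at r=100 um.

The live cycle divides a proliferative cell with probability 1-exp(-b*dt)
per update, b = ln(2)/doubling_time (default 1,320 min = 22 h).  Death is a
fixed-duration countdown: an apoptotic or necrotic cell leaves the alive
count immediately, keeps exerting mechanical forces while dying, and is
removed from the arena when its clock expires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .boolnet import BooleanNetwork
from .receptor import ReceptorParams, ReceptorState
from .treatment import VariabilityConfig, sample_param_arrays

__all__ = [
    "Population",
    "Cell",
    "STATUS",
    "initialize_disc",
    "initialize_spheroid",
    "advance_cycle",
    "start_death",
    "update_death",
    "mechanics_step",
    "update_phenotype",
    "unconstrained_growth_curve",
    "fit_doubling_time",
    "DEFAULT_CELL_VOLUME",
    "DISC_SPACING_FACTOR",
    "SPHEROID_SPACING_FACTOR",
]

STATUS = {"alive": 0, "apoptotic": 1, "necrotic": 2, "removed": 3}
_STATUS_NAME = {v: k for k, v in STATUS.items()}

DEFAULT_CELL_VOLUME = 2494.0  # um^3, radius ~8.41 um
DISC_SPACING_FACTOR = 0.95
SPHEROID_SPACING_FACTOR = 1.0
APOPTOSIS_DURATION = 516.0    # min
NECROSIS_DURATION = 1440.0    # min
DOUBLING_TIME = 1320.0        # min (22 h)


@dataclass
class Cell:
    """Read-only view of one agent (see Population arrays for the truth)."""

    id: int
    position: np.ndarray
    radius: float
    status: str
    death_clock: float
    receptor: ReceptorState
    params: ReceptorParams
    division_eligible: bool


class Population:
    """Structure-of-arrays container for the cell agents."""

    def __init__(self, positions: np.ndarray, dims: int,
                 cell_volume: float = DEFAULT_CELL_VOLUME):
        n = len(positions)
        self.dims = dims
        self.cell_volume = float(cell_volume)
        r = (3.0 * cell_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
        self.positions = np.asarray(positions, dtype=np.float64).reshape(n, 3)
        self.ids = np.arange(n, dtype=np.int64)
        self.radius = np.full(n, r)
        self.status = np.zeros(n, dtype=np.int8)
        self.death_clock = np.zeros(n)
        self.division_eligible = np.zeros(n, dtype=np.uint8)
        self.next_id = n
        # intracellular state (filled by attach_intracellular)
        self.base_params = ReceptorParams()
        self.re = np.full(n, self.base_params.R_total)
        self.res = np.zeros(n)
        self.ris = np.zeros(n)
        self.kb = np.full(n, self.base_params.k_bind)
        self.ke = np.full(n, self.base_params.k_endo)
        self.kr = np.full(n, self.base_params.k_recycle)
        self.net: BooleanNetwork | None = None
        self.net_values = np.zeros((n, 0), dtype=np.uint8)
        self.seed = 0
        self._make_keys()

    def _make_keys(self):
        self.ctmc_keys = _kernels.make_keys(self.seed, self.ids,
                                            _kernels.PUR_CTMC)
        self.ctmc_counters = np.zeros(len(self.ids), dtype=np.uint64)
        self.cycle_keys = _kernels.make_keys(self.seed, self.ids,
                                             _kernels.PUR_CYCLE)
        self.cycle_counters = np.zeros(len(self.ids), dtype=np.uint64)

    # -- intracellular wiring ------------------------------------------------
    def attach_intracellular(self, net: BooleanNetwork,
                             params: ReceptorParams,
                             variability: VariabilityConfig | None = None,
                             seed: int = 0,
                             initial_on: tuple[str, ...] = ("Proliferation",)):
        """Give every cell a receptor state, kinetic params and network state.

        With variability, each cell's k_bind/k_endo/k_recycle are drawn from
        the truncated relative-sd normal; the draw stream is keyed by the
        seed only, and daughters inherit their parent's values.
        """
        n = len(self.ids)
        self.seed = int(seed)
        self.base_params = params
        self.net = net
        rng = np.random.Generator(np.random.Philox(key=[seed, 0xA11CE]))
        if variability is not None and variability.sigma > 0:
            self.kb, self.ke, self.kr = sample_param_arrays(
                params, variability, n, rng)
        else:
            self.kb = np.full(n, params.k_bind)
            self.ke = np.full(n, params.k_endo)
            self.kr = np.full(n, params.k_recycle)
        self.re = np.full(n, params.R_total)
        self.res = np.zeros(n)
        self.ris = np.zeros(n)
        self.net_values = np.tile(net.initial_state(initial_on).values,
                                  (n, 1))
        self.division_eligible = np.ones(n, dtype=np.uint8)
        self._make_keys()

    # -- bookkeeping ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    @property
    def alive(self) -> np.ndarray:
        return self.status == STATUS["alive"]

    def counts(self) -> dict[str, int]:
        return {name: int((self.status == code).sum())
                for name, code in STATUS.items()}

    def alive_count(self) -> int:
        return int(self.alive.sum())

    def total_created(self) -> int:
        return self.next_id

    def cell(self, i: int) -> Cell:
        return Cell(
            id=int(self.ids[i]), position=self.positions[i].copy(),
            radius=float(self.radius[i]),
            status=_STATUS_NAME[int(self.status[i])],
            death_clock=float(self.death_clock[i]),
            receptor=ReceptorState(self.re[i], self.res[i], self.ris[i]),
            params=ReceptorParams(
                k_bind=self.kb[i], k_endo=self.ke[i], k_recycle=self.kr[i],
                R_total=self.base_params.R_total,
                activation_threshold=self.base_params.activation_threshold),
            division_eligible=bool(self.division_eligible[i]))

    def snapshot_dataframe(self):
        import pandas as pd

        cols = {
            "id": self.ids, "x": self.positions[:, 0],
            "y": self.positions[:, 1], "z": self.positions[:, 2],
            "status": [_STATUS_NAME[int(s)] for s in self.status],
            "Re": self.re, "Re_star": self.res, "Ri_star": self.ris,
        }
        if self.net is not None and self.net_values.size:
            for idx, name in enumerate(self.net.names):
                cols[f"node_{name}"] = self.net_values[:, idx]
        return pd.DataFrame(cols)

    def _append(self, positions, parent_idx):
        """Append daughters inheriting the parent's kinetic parameters."""
        m = len(parent_idx)
        if m == 0:
            return
        new_ids = np.arange(self.next_id, self.next_id + m, dtype=np.int64)
        self.next_id += m
        self.ids = np.concatenate([self.ids, new_ids])
        self.positions = np.vstack([self.positions, positions])
        self.radius = np.concatenate([self.radius, self.radius[parent_idx]])
        self.status = np.concatenate(
            [self.status, np.zeros(m, dtype=np.int8)])
        self.death_clock = np.concatenate([self.death_clock, np.zeros(m)])
        self.division_eligible = np.concatenate(
            [self.division_eligible, np.ones(m, dtype=np.uint8)])
        self.kb = np.concatenate([self.kb, self.kb[parent_idx]])
        self.ke = np.concatenate([self.ke, self.ke[parent_idx]])
        self.kr = np.concatenate([self.kr, self.kr[parent_idx]])
        # daughters start with a full free-receptor pool and a naive network
        self.re = np.concatenate(
            [self.re, np.full(m, self.base_params.R_total)])
        self.res = np.concatenate([self.res, np.zeros(m)])
        self.ris = np.concatenate([self.ris, np.zeros(m)])
        if self.net is not None:
            fresh = np.tile(self.net.initial_state(("Proliferation",)).values,
                            (m, 1))
            self.net_values = np.vstack([self.net_values, fresh]) \
                if self.net_values.size else fresh
        self.ctmc_keys = np.concatenate(
            [self.ctmc_keys,
             _kernels.make_keys(self.seed, new_ids, _kernels.PUR_CTMC)])
        self.ctmc_counters = np.concatenate(
            [self.ctmc_counters, np.zeros(m, dtype=np.uint64)])
        self.cycle_keys = np.concatenate(
            [self.cycle_keys,
             _kernels.make_keys(self.seed, new_ids, _kernels.PUR_CYCLE)])
        self.cycle_counters = np.concatenate(
            [self.cycle_counters, np.zeros(m, dtype=np.uint64)])


# ---------------------------------------------------------------------------
# initial geometries
# ---------------------------------------------------------------------------

def initialize_disc(radius: float,
                    spacing_factor: float = DISC_SPACING_FACTOR,
                    cell_volume: float = DEFAULT_CELL_VOLUME) -> Population:
    """Hexagonally packed monolayer disc centred at the origin.

    Lattice sites with |site| <= radius are kept; radius 0 gives one cell.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    cell_r = (3.0 * cell_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    a = spacing_factor * 2.0 * cell_r
    dy = np.sqrt(3.0) / 2.0 * a
    pts = [(0.0, 0.0)] if radius == 0 else []
    if radius > 0:
        jmax = int(np.ceil(radius / dy)) + 1
        imax = int(np.ceil(radius / a)) + 1
        for j in range(-jmax, jmax + 1):
            y = j * dy
            off = 0.5 * a if j % 2 else 0.0
            for i in range(-imax, imax + 1):
                x = i * a + off
                if x * x + y * y <= radius * radius:
                    pts.append((x, y))
    positions = np.zeros((len(pts), 3))
    positions[:, :2] = pts
    return Population(positions, dims=2, cell_volume=cell_volume)


def initialize_spheroid(radius: float,
                        spacing_factor: float = SPHEROID_SPACING_FACTOR,
                        cell_volume: float = DEFAULT_CELL_VOLUME
                        ) -> Population:
    """Layered hexagonally packed spheroid centred at the origin.

    x/z spacing r*sqrt(3), y spacing 2r with row/layer parity offsets
    (r = spacing_factor * cell radius); sites with |site| < radius are kept
    and radius 0 gives a single cell.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    cell_r = spacing_factor * (3.0 * cell_volume / (4.0 * np.pi)) ** (1. / 3.)
    xs = cell_r * np.sqrt(3.0)
    ys = 2.0 * cell_r
    zs = cell_r * np.sqrt(3.0)
    pts = []
    if radius == 0:
        pts.append((0.0, 0.0, 0.0))
    else:
        nz = int(np.ceil(2 * radius / zs)) + 1
        nx = int(np.ceil(2 * radius / xs)) + 1
        ny = int(np.ceil(2 * radius / ys)) + 1
        for zc in range(nz):
            z = -radius + zc * zs
            if z >= radius:
                break
            for xc in range(nx):
                x = -radius + xc * xs
                if x >= radius:
                    break
                for yc in range(ny):
                    y = -radius + yc * ys
                    if y >= radius:
                        break
                    px = x + (zc % 2) * 0.5 * cell_r
                    py = y + (xc % 2) * cell_r
                    if px * px + py * py + z * z < radius * radius:
                        pts.append((px, py, z))
    return Population(np.array(pts).reshape(-1, 3), dims=3,
                      cell_volume=cell_volume)


# ---------------------------------------------------------------------------
# cycle, death, phenotype, mechanics
# ---------------------------------------------------------------------------

def advance_cycle(pop: Population, dt: float,
                  doubling_time: float = DOUBLING_TIME) -> int:
    """Divide eligible alive cells with probability 1-exp(-b*dt).

    b = ln2/doubling_time.  Daughters are placed one cell radius away in a
    uniform random direction (in-plane for 2-D populations), inherit the
    parent's kinetic parameters, and start with a naive network state and a
    full free-receptor pool.  Returns the number of divisions.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if dt == 0:
        return 0
    b = np.log(2.0) / doubling_time
    p = 1.0 - np.exp(-b * dt)
    eligible = ((pop.status == STATUS["alive"])
                & (pop.division_eligible == 1)).astype(np.uint8)
    div, u1, u2 = _kernels.division_draws(eligible, p, pop.cycle_keys,
                                          pop.cycle_counters)
    idx = np.nonzero(div)[0]
    if len(idx) == 0:
        return 0
    theta = 2.0 * np.pi * u1[idx]
    if pop.dims == 2:
        direction = np.column_stack(
            [np.cos(theta), np.sin(theta), np.zeros(len(idx))])
    else:
        z = 2.0 * u2[idx] - 1.0
        rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
        direction = np.column_stack(
            [rho * np.cos(theta), rho * np.sin(theta), z])
    newpos = pop.positions[idx] + direction * pop.radius[idx, None]
    pop._append(newpos, idx)
    return len(idx)


def start_death(pop: Population, i: int, mode: str,
                apoptosis_duration: float = APOPTOSIS_DURATION,
                necrosis_duration: float = NECROSIS_DURATION) -> None:
    """Commit an alive cell to apoptosis or necrosis; no-op if already dying."""
    if mode not in ("apoptotic", "necrotic"):
        raise ValueError(f"unknown death mode '{mode}'")
    if pop.status[i] != STATUS["alive"]:
        return
    pop.status[i] = STATUS[mode]
    pop.death_clock[i] = (apoptosis_duration if mode == "apoptotic"
                          else necrosis_duration)
    pop.division_eligible[i] = 0


def update_death(pop: Population, dt: float) -> None:
    """Advance death clocks; expired dying cells become removed."""
    dying = (pop.status == STATUS["apoptotic"]) | \
            (pop.status == STATUS["necrotic"])
    pop.death_clock[dying] -= dt
    done = dying & (pop.death_clock <= 0)
    pop.status[done] = STATUS["removed"]


def update_phenotype(pop: Population) -> None:
    """Map each alive cell's fate readout to agent behaviour.

    Death readouts take precedence over proliferation; proliferative cells
    become division-eligible, quiescent ones idle.  Both death nodes ON in
    any cell aborts (broken network).
    """
    if pop.net is None or not pop.net.readouts:
        return
    ro = pop.net.readouts
    alive = pop.alive
    apo = pop.net_values[:, ro["apoptosis"]] == 1
    nec = pop.net_values[:, ro["nonacd"]] == 1
    if np.any(alive & apo & nec):
        raise ValueError("both death readouts ON; broken network logic")
    for i in np.nonzero(alive & apo)[0]:
        start_death(pop, i, "apoptotic")
    for i in np.nonzero(alive & nec)[0]:
        start_death(pop, i, "necrotic")
    prolif = pop.net_values[:, ro["proliferation"]] == 1
    still = pop.alive
    pop.division_eligible[still] = prolif[still].astype(np.uint8)
    pop.division_eligible[~still] = 0


def mechanics_step(pop: Population, dt: float, k_rep: float = 10.0,
                   nsteps: int = 1) -> None:
    """Overdamped pairwise-repulsion relaxation for all non-removed cells."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    active = pop.status != STATUS["removed"]
    ok = _kernels.mechanics_steps(pop.positions, pop.radius,
                                  active, pop.dims, k_rep, dt, nsteps)
    if not ok:
        raise FloatingPointError("non-finite force in mechanics step")


# ---------------------------------------------------------------------------
# growth calibration helpers
# ---------------------------------------------------------------------------

def unconstrained_growth_curve(n0: int, horizon: float, dt: float = 6.0,
                               seed: int = 0,
                               doubling_time: float = DOUBLING_TIME):
    """Alive-count curve of pure exponential growth (no death, no mechanics).

    Returns (times, counts) sampled after every dt window.
    """
    pop = Population(np.zeros((n0, 3)), dims=3)
    pop.seed = int(seed)
    pop._make_keys()
    pop.division_eligible[:] = 1
    times = [0.0]
    counts = [n0]
    t = 0.0
    while t < horizon - 1e-9:
        win = min(dt, horizon - t)
        advance_cycle(pop, win, doubling_time)
        t += win
        times.append(t)
        counts.append(pop.alive_count())
    return np.array(times), np.array(counts, dtype=float)


def fit_doubling_time(times, counts) -> float:
    """Doubling time (hours) from a log-linear fit of the growth curve."""
    slope = np.polyfit(times, np.log(counts), 1)[0]
    return float(np.log(2.0) / slope / 60.0)
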