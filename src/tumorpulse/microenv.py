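"""Regular-grid reaction–diffusion microenvironment.

A :class:`ScalarField` holds one diffusible substrate (TNF by default, in
ng/L) on a uniform 2-D or 3-D voxel grid centered at the origin.  Transport is
solved by operator splitting: one implicit (backward-Euler) diffusion pass per
axis via a tridiagonal solve with reflecting (no-flux) ends, followed by a
backward-Euler decay c <- c/(1 + lambda*dt).  The implicit scheme is
unconditionally stable and preserves non-negativity.

Pulsed supply enters through Dirichlet boundary voxels while a pulse is
active (:func:`apply_boundary_pulse`); outside pulses the boundary reverts to
no-flux.  All mass entering or leaving the field is booked on the field's
ledger (``supplied``, ``decayed``, ``consumed``) so a closed balance
supplied - decayed - consumed - remaining + initial = 0 holds to round-off.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .treatment import PulseSchedule, pulse_active

__all__ = [
    "ScalarField",
    "diffuse_decay_step",
    "apply_boundary_pulse",
    "consume_at",
    "concentration_at",
]


class ScalarField:
    """A diffusible substrate on a regular voxel grid.

    Parameters
    ----------
    name:
        Substrate label (e.g. ``"tnf"``).
    dims:
        2 or 3.
    voxel_size:
        Edge length of the cubic voxels, in micrometres.
    half_extent:
        Half-width of the (cubic) domain per axis in micrometres; the domain
        is centred at the origin and each axis spans ``[-half, half)`` with
        half-open voxel intervals.
    diffusion_coefficient:
        In um^2/min.
    decay_rate:
        First-order decay constant, 1/min.
    """

    def __init__(self, name: str, dims: int, voxel_size: float,
                 half_extent: float, diffusion_coefficient: float = 1200.0,
                 decay_rate: float = 0.0275):
        if dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if voxel_size <= 0 or half_extent <= 0:
            raise ValueError("voxel_size and half_extent must be positive")
        self.name = name
        self.dims = dims
        self.voxel_size = float(voxel_size)
        nvox = max(3, int(np.ceil(2.0 * half_extent / voxel_size)))
        self.shape = (nvox,) * dims
        self.origin = -0.5 * nvox * voxel_size  # lower corner, every axis
        self.concentrations = np.zeros(self.shape, dtype=np.float64)
        self.diffusion_coefficient = float(diffusion_coefficient)
        self.decay_rate = float(decay_rate)
        # voxel volume is always cubic (2-D fields carry one voxel of depth)
        self.voxel_volume = self.voxel_size ** 3
        self.supplied = 0.0
        self.decayed = 0.0
        self.consumed = 0.0

    # -- geometry helpers ---------------------------------------------------
    @property
    def extent(self) -> tuple[float, float]:
        """(min, max) coordinate per axis in micrometres."""
        return (self.origin, -self.origin)

    def voxel_index(self, position) -> tuple[int, ...]:
        """Containing voxel via half-open intervals [lo, hi) per axis."""
        position = np.asarray(position, dtype=float)[: self.dims]
        idx = np.floor((position - self.origin) / self.voxel_size).astype(int)
        if np.any(idx < 0) or np.any(idx >= self.shape[0]):
            raise ValueError(
                f"position {tuple(position)} outside the domain "
                f"[{self.origin}, {-self.origin}) um of field '{self.name}'")
        return tuple(idx)

    def total_mass(self) -> float:
        """Sum over voxels times voxel volume (ng*um^3/L)."""
        return float(self.concentrations.sum()) * self.voxel_volume

    def boundary_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        for ax in range(self.dims):
            sl = [slice(None)] * self.dims
            sl[ax] = 0
            mask[tuple(sl)] = True
            sl[ax] = -1
            mask[tuple(sl)] = True
        return mask

    def ledger(self) -> dict:
        return {
            "supplied": self.supplied,
            "decayed": self.decayed,
            "consumed": self.consumed,
            "remaining": self.total_mass(),
        }

    def snapshot_dataframe(self):
        """Voxel table (index, x, y, z, concentration)."""
        import pandas as pd

        grids = np.meshgrid(
            *[self.origin + (np.arange(n) + 0.5) * self.voxel_size
              for n in self.shape], indexing="ij")
        cols = {"voxel": np.arange(self.concentrations.size)}
        for ax, label in zip(range(self.dims), "xyz"):
            cols[label] = grids[ax].ravel()
        if self.dims == 2:
            cols["z"] = np.zeros(self.concentrations.size)
        cols["concentration"] = self.concentrations.ravel()
        return pd.DataFrame(cols)


def diffuse_decay_step(field: ScalarField, dt: float) -> ScalarField:
    """One operator-split transport step: implicit diffusion, then decay.

    Diffusion is dimension-split: a backward-Euler tridiagonal solve per axis
    with no-flux ends (mass-conserving).  Decay uses the backward-Euler closed
    form c/(1 + lambda*dt) and books the removed mass on the field ledger.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    c = field.concentrations
    if not np.all(np.isfinite(c)):
        bad = tuple(int(i) for i in np.argwhere(~np.isfinite(c))[0])
        raise FloatingPointError(
            f"non-finite concentration in field '{field.name}' at voxel "
            f"{bad}")
    a = field.diffusion_coefficient * dt / field.voxel_size ** 2
    n = field.shape[0]
    for ax in range(field.dims):
        moved = np.moveaxis(c, ax, 0)
        flat = np.ascontiguousarray(moved.reshape(n, -1))
        _kernels.thomas_axis0(flat, a)
        np.moveaxis(c, ax, 0)[...] = flat.reshape(moved.shape)
    lam = field.decay_rate
    if lam > 0:
        before = c.sum()
        c *= 1.0 / (1.0 + lam * dt)
        field.decayed += (before - c.sum()) * field.voxel_volume
    return field


def apply_boundary_pulse(field: ScalarField, schedule: PulseSchedule,
                         t: float) -> ScalarField:
    """Set boundary voxels to the pulse concentration while a pulse is active.

    The mass difference is booked as supplied; outside the pulse the call is a
    no-op and the boundary behaves as no-flux.
    """
    if pulse_active(schedule, t):
        mask = field.boundary_mask()
        delta = schedule.concentration - field.concentrations[mask]
        field.supplied += float(delta.sum()) * field.voxel_volume
        field.concentrations[mask] = schedule.concentration
    return field


def apply_uniform_pulse(field: ScalarField, schedule: PulseSchedule,
                        t: float) -> ScalarField:
    """Alternative supply mode: bathe the whole domain during a pulse."""
    if pulse_active(schedule, t):
        delta = schedule.concentration - field.concentrations
        np.maximum(delta, 0.0, out=delta)
        field.supplied += float(delta.sum()) * field.voxel_volume
        np.maximum(field.concentrations, schedule.concentration,
                   out=field.concentrations)
    return field


def consume_at(field: ScalarField, position, amount: float) -> float:
    """Remove up to `amount` (ng*um^3/L) of mass from the containing voxel.

    The voxel concentration is floored at zero; the mass actually removed is
    returned and booked on the ledger.
    """
    if amount < 0:
        raise ValueError("amount must be non-negative")
    idx = field.voxel_index(position)
    avail = field.concentrations[idx] * field.voxel_volume
    removed = min(avail, amount)
    field.concentrations[idx] -= removed / field.voxel_volume
    if field.concentrations[idx] < 0:  # round-off guard
        field.concentrations[idx] = 0.0
    field.consumed += removed
    return removed


def concentration_at(field: ScalarField, position) -> float:
    """Nearest-voxel (no interpolation) concentration lookup."""
    return float(field.concentrations[field.voxel_index(position)])


def consume_at_voxels(field: ScalarField, voxel_indices: np.ndarray,
                      amounts: np.ndarray) -> np.ndarray:
    """Vectorised uptake used by the simulation loop.

    voxel_indices is (n, dims) integer; several cells may share a voxel, in
    which case the available mass is split proportionally to demand.
    """
    removed = np.zeros(len(amounts))
    if len(amounts) == 0:
        return removed
    flat = np.ravel_multi_index(voxel_indices.T, field.shape)
    vol = field.voxel_volume
    demand = np.bincount(flat, weights=amounts,
                         minlength=field.concentrations.size)
    avail = field.concentrations.ravel() * vol
    take = np.minimum(demand, avail)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(demand > 0, take / demand, 0.0)
    removed = amounts * frac[flat]
    newc = (avail - take) / vol
    field.concentrations.ravel()[:] = np.maximum(newc, 0.0)
    field.consumed += float(take.sum())
    return removed
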