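"""Leaky integrate-and-fire neuron dynamics on a discrete simulation grid.

The membrane potential V of a point neuron with capacitance ``Cm`` and leak
conductance ``gl`` (the reciprocal of the membrane resistance ``Rm``) obeys

    Cm * dV/dt + gl * (V - V0) = I_inj(t),

with resting potential ``V0 = 0``.  Input currents are Dirac spike trains,
so between events the potential decays exponentially with the membrane time
constant ``tau_m = Cm / gl``, and each event of amplitude ``w`` injects a
potential step ``w / Cm``.  Both facts are exact, which is why the grid
simulation below uses exact exponential decay per step plus instantaneous
charge injection rather than an Euler scheme: for Dirac-train inputs the
discretisation introduces no integration error, only event-time snapping.

When the pre-reset potential H(t) reaches the threshold ``Vth`` the neuron
emits a unit spike and resets.  Two reset rules are supported:

* ``linear`` (soft reset): V <- H - Vth, retaining the surplus above
  threshold.  This conserves injected charge and is the variant that maps
  exactly onto a ReLU unit.
* ``zero``: V <- Vreset, discarding the surplus.

At most one output spike is emitted per grid step; in the pathological case
H >= 2*Vth the surplus (linear mode) is carried forward and fires on a
later step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .errors import AlignmentError, InvalidParameterError

__all__ = [
    "SimGrid",
    "LIFParams",
    "SpikeTrain",
    "MembraneTrace",
    "closed_form_potential",
    "apply_reset",
    "simulate",
]

#: Absolute slack on threshold comparisons.  Weighted sums such as 0.3 + 0.2
#: accumulate float error of order 1e-16 per event; without slack a neuron
#: that mathematically reaches Vth exactly would fail to fire.
THRESHOLD_TOL = 1e-9


@dataclass(frozen=True)
class SimGrid:
    """Uniform simulation grid: step ``dt`` over the window ``(0, t_window]``.

    Grid step ``i`` (0-based) carries the time stamp ``(i + 1) * dt``; events
    are snapped to the nearest step, ties resolved toward the earlier step.
    """

    dt: float = 0.01
    t_window: float = 3.0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise InvalidParameterError(f"dt must be positive, got {self.dt}")
        if self.t_window < self.dt:
            raise InvalidParameterError(
                f"t_window ({self.t_window}) must be >= dt ({self.dt})"
            )

    @property
    def n_steps(self) -> int:
        return int(round(self.t_window / self.dt))

    @property
    def times(self) -> np.ndarray:
        """Time stamps of all grid steps, ``dt, 2*dt, ..., t_window``."""
        return (np.arange(self.n_steps) + 1.0) * self.dt

    def step_of(self, t: float) -> int:
        """Nearest grid step for time ``t`` in (0, t_window]; ties go earlier."""
        if t <= 0 or t > self.t_window * (1 + 1e-9) + 0.5 * self.dt:
            raise AlignmentError(f"time {t} outside (0, {self.t_window}]")
        idx = int(np.floor(t / self.dt + 0.5 - 1e-12)) - 1
        return min(max(idx, 0), self.n_steps - 1)


@dataclass(frozen=True)
class LIFParams:
    """Biophysical parameter set of a single spiking neuron.

    ``gl`` is the leak conductance, read as 1/Rm; ``gl = 0`` is the leak-free
    (perfect integrator) limit in which ``tau_m`` is undefined.
    """

    cm: float = 1.0
    gl: float = 0.0
    v_th: float = 1.0
    v_reset: float = 0.0
    v_rest: float = 0.0
    reset_mode: str = "linear"

    def __post_init__(self) -> None:
        if not self.cm > 0:
            raise InvalidParameterError(f"Cm must be positive, got {self.cm}")
        if self.gl < 0:
            raise InvalidParameterError(f"gl must be >= 0, got {self.gl}")
        if not self.v_th > 0:
            raise InvalidParameterError(f"Vth must be positive, got {self.v_th}")
        if self.reset_mode not in ("linear", "zero"):
            raise InvalidParameterError(
                f"reset_mode must be 'linear' or 'zero', got {self.reset_mode!r}"
            )

    @property
    def tau_m(self) -> float | None:
        """Membrane time constant Cm/gl; ``None`` in the leak-free limit."""
        return self.cm / self.gl if self.gl > 0 else None

    @property
    def rm(self) -> float | None:
        """Membrane resistance 1/gl; ``None`` in the leak-free limit."""
        return 1.0 / self.gl if self.gl > 0 else None

    def with_reset(self, mode: str) -> "LIFParams":
        return replace(self, reset_mode=mode)


@dataclass(frozen=True)
class SpikeTrain:
    """Timed, amplitude-tagged point events aligned to a simulation grid."""

    times: np.ndarray
    amplitudes: np.ndarray
    grid: SimGrid

    def __post_init__(self) -> None:
        times = np.atleast_1d(np.asarray(self.times, dtype=float))
        amps = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "amplitudes", amps)
        if times.shape != amps.shape or times.ndim != 1:
            raise AlignmentError("times and amplitudes must be equal-length 1-D")
        if times.size:
            if times.min() <= 0 or times.max() > self.grid.t_window * (1 + 1e-9):
                raise AlignmentError(
                    f"event times must lie in (0, {self.grid.t_window}]"
                )
            if np.any(np.diff(times) < 0):
                raise AlignmentError("event times must be sorted")

    @classmethod
    def empty(cls, grid: SimGrid) -> "SpikeTrain":
        return cls(np.empty(0), np.empty(0), grid)

    @classmethod
    def from_steps(
        cls, steps: np.ndarray, grid: SimGrid, amplitudes: np.ndarray | float = 1.0
    ) -> "SpikeTrain":
        steps = np.asarray(steps, dtype=int)
        amps = np.broadcast_to(np.asarray(amplitudes, dtype=float), steps.shape)
        return cls((steps + 1.0) * grid.dt, amps.copy(), grid)

    @property
    def n_events(self) -> int:
        return int(self.times.size)

    def __len__(self) -> int:
        return self.n_events

    @property
    def total_amplitude(self) -> float:
        return float(self.amplitudes.sum())

    def steps(self) -> np.ndarray:
        """Grid step index of every event (nearest step, ties earlier)."""
        if not self.times.size:
            return np.empty(0, dtype=int)
        idx = np.floor(self.times / self.grid.dt + 0.5 - 1e-12).astype(int) - 1
        return np.clip(idx, 0, self.grid.n_steps - 1)

    def to_drive(self, strict: bool = False) -> np.ndarray:
        """Per-step summed event amplitude, shape ``(n_steps,)``.

        With ``strict=True`` events must sit exactly on grid stamps
        (tolerance ``dt * 1e-6``), otherwise an :class:`AlignmentError`
        is raised.
        """
        steps = self.steps()
        if strict and self.times.size:
            stamps = (steps + 1.0) * self.grid.dt
            if np.max(np.abs(stamps - self.times)) > self.grid.dt * 1e-6:
                raise AlignmentError("events are not aligned to the grid")
        drive = np.zeros(self.grid.n_steps)
        np.add.at(drive, steps, self.amplitudes)
        return drive

    def scaled(self, factor: float) -> "SpikeTrain":
        return SpikeTrain(self.times, self.amplitudes * factor, self.grid)

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.times, self.amplitudes]),
            delimiter=",",
            header="time,amplitude",
            comments="",
        )

    @classmethod
    def from_csv(cls, path, grid: SimGrid) -> "SpikeTrain":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        if data.size == 0:
            return cls.empty(grid)
        return cls(data[:, 0], data[:, 1], grid)


@dataclass(frozen=True)
class MembraneTrace:
    """Per-step record of one simulated neuron.

    ``pre_reset`` is H(t) (potential after decay and injection, before any
    reset), ``potential`` is V(t) (after reset), ``spikes`` flags the steps
    that emitted an output spike.
    """

    pre_reset: np.ndarray
    potential: np.ndarray
    spikes: np.ndarray
    params: LIFParams
    grid: SimGrid

    @property
    def n_spikes(self) -> int:
        return int(np.count_nonzero(self.spikes))

    @property
    def output_train(self) -> SpikeTrain:
        """Emitted unit-amplitude spikes as a grid-aligned train."""
        steps = np.flatnonzero(self.spikes)
        return SpikeTrain.from_steps(steps, self.grid)

    @property
    def final_potential(self) -> float:
        return float(self.potential[-1]) if self.potential.size else 0.0

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack(
                [self.grid.times, self.pre_reset, self.potential, self.spikes]
            ),
            delimiter=",",
            header="time,H,V,S",
            comments="",
        )


def closed_form_potential(
    params: LIFParams, weight: float, period: float, n: int
) -> float:
    """Membrane potential just after the ``n``-th spike of a periodic input.

    For an amplitude-``weight`` train of period ``T`` with no threshold, each
    incoming spike injects ``weight/Cm`` and then decays, so the potential
    immediately after spike ``n`` is the geometric sum

        V(n T+) = (weight / Cm) * (1 - exp(-n T / tau_m)) / (1 - exp(-T / tau_m)),

    reducing to ``n * weight / Cm`` in the leak-free limit ``gl = 0``.
    """
    if n < 1 or int(n) != n:
        raise InvalidParameterError(f"n must be a positive integer, got {n}")
    if not period > 0:
        raise InvalidParameterError(f"period must be positive, got {period}")
    if params.gl == 0:
        return n * weight / params.cm
    r = np.exp(-period / params.tau_m)
    return float(weight / params.cm * (1.0 - r**n) / (1.0 - r))


def apply_reset(h: float, fired: bool, params: LIFParams) -> float:
    """Post-spike potential: subtract Vth (linear) or jump to Vreset (zero)."""
    if not fired:
        return h
    if params.reset_mode == "linear":
        return h - params.v_th
    return params.v_reset


def _simulate_drive(
    drive: np.ndarray,
    cm: float,
    gl: np.ndarray | float,
    v_th: float,
    reset_mode: str,
    dt: float,
    v_reset: float = 0.0,
    v_rest: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised grid simulation of ``n_units`` neurons sharing one drive grid.

    ``drive`` has shape ``(n_units, n_steps)`` holding the summed event
    amplitude per step; ``gl`` may be scalar or per-unit.  Returns
    ``(H, V, S)`` arrays of the same shape.
    """
    drive = np.atleast_2d(np.asarray(drive, dtype=float))
    n_units, n_steps = drive.shape
    gl = np.broadcast_to(np.asarray(gl, dtype=float), (n_units,))
    decay = np.exp(-dt * gl / cm)
    h_out = np.empty_like(drive)
    v_out = np.empty_like(drive)
    s_out = np.zeros(drive.shape, dtype=bool)
    v = np.full(n_units, float(v_reset))
    thr = v_th - THRESHOLD_TOL
    for t in range(n_steps):
        v = v_rest + (v - v_rest) * decay
        h = v + drive[:, t] / cm
        fired = h >= thr
        if reset_mode == "linear":
            v = np.where(fired, h - v_th, h)
        else:
            v = np.where(fired, v_reset, h)
        h_out[:, t] = h
        v_out[:, t] = v
        s_out[:, t] = fired
    return h_out, v_out, s_out


def simulate(train: SpikeTrain, params: LIFParams, grid: SimGrid) -> MembraneTrace:
    """Simulate one neuron over the grid window driven by ``train``.

    Per step: exact exponential decay toward the resting potential, then
    injection of the step's summed event amplitudes divided by Cm, giving
    H(t); if H(t) >= Vth one unit output spike is emitted and the potential
    resets according to ``params.reset_mode``.
    """
    if train.grid != grid:
        raise AlignmentError("train grid differs from the simulation grid")
    drive = train.to_drive(strict=True)
    h, v, s = _simulate_drive(
        drive[None, :],
        params.cm,
        params.gl,
        params.v_th,
        params.reset_mode,
        grid.dt,
        v_reset=params.v_reset,
        v_rest=params.v_rest,
    )
    return MembraneTrace(h[0], v[0], s[0], params, grid)
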