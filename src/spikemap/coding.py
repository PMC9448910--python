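"""Rate coding: real values <-> periodic spike trains.

A value ``x`` in [0, 1] is represented by a periodic unit-amplitude train at
frequency ``f = x * f_max`` inside the window ``(0, T_w]``; decoding counts
events and divides by the window length.  The count quantisation makes the
decode error at most ``1/T_w``, which is the behavioural error bound the
whole ANN/SNN equivalence rests on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, RangeError, ShapeError
from .neuron import SimGrid, SpikeTrain

__all__ = ["RateCode", "encode_rate", "decode_rate", "weighted_sum_trains"]


@dataclass(frozen=True)
class RateCode:
    """Rate-coding configuration: maximum frequency ``f_max`` on a grid.

    Requires at least one grid step per period at full scale
    (``1/f_max >= dt``), so a train can never outrun the grid.
    """

    f_max: float = 10.0
    grid: SimGrid = SimGrid()

    def __post_init__(self) -> None:
        if not self.f_max > 0:
            raise InvalidParameterError(f"f_max must be positive, got {self.f_max}")
        if 1.0 / self.f_max < self.grid.dt * (1 - 1e-9):
            raise InvalidParameterError(
                f"1/f_max ({1.0 / self.f_max}) must be >= dt ({self.grid.dt})"
            )


def encode_spike_steps(x: float, code: RateCode) -> np.ndarray:
    """Grid step indices of the encoded train for ``x`` (helper for tensors).

    Spike ``j`` sits at time ``j / f`` for ``j = 1..floor(T_w * f)``, snapped
    to the nearest grid step (ties toward the earlier step).
    """
    if x < 0 or x > 1:
        raise RangeError(f"encoder input must lie in [0, 1], got {x}")
    f = x * code.f_max
    grid = code.grid
    n = int(np.floor(grid.t_window * f + 1e-9))
    if n == 0:
        return np.empty(0, dtype=int)
    times = np.arange(1, n + 1) / f
    idx = np.floor(times / grid.dt + 0.5 - 1e-12).astype(int) - 1
    return np.clip(idx, 0, grid.n_steps - 1)


def encode_rate(x: float, code: RateCode) -> SpikeTrain:
    """Encode ``x`` in [0, 1] as a periodic unit-amplitude spike train."""
    return SpikeTrain.from_steps(encode_spike_steps(x, code), code.grid)


def decode_rate(train: SpikeTrain, t_window: float | None = None) -> float:
    """Event count divided by the window length, in Hz."""
    t = train.grid.t_window if t_window is None else t_window
    if not t > 0:
        raise InvalidParameterError(f"window must be positive, got {t}")
    return train.n_events / t


def weighted_sum_trains(
    trains: list[SpikeTrain], weights: np.ndarray | list[float]
) -> SpikeTrain:
    """Superpose presynaptic trains, scaling each train's amplitudes by its
    weight.  Coincident events stay separate; the simulator sums them."""
    weights = np.asarray(weights, dtype=float)
    if len(trains) != weights.size:
        raise ShapeError(
            f"{len(trains)} trains but {weights.size} weights"
        )
    if not trains:
        raise ShapeError("need at least one train")
    grid = trains[0].grid
    for tr in trains[1:]:
        if tr.grid != grid:
            raise ShapeError("all trains must share one grid")
    times = np.concatenate([tr.times for tr in trains])
    amps = np.concatenate(
        [tr.amplitudes * w for tr, w in zip(trains, weights)]
    )
    order = np.argsort(times, kind="stable")
    return SpikeTrain(times[order], amps[order], grid)
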