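"""Spiking and reference (ReLU) dense, 2-D convolution and max-pool layers.

A spiking layer receives a :class:`SpikeTensor` (a grid of unit-amplitude
spike trains), forms each output unit's drive as the weighted superposition
of its receptive-field trains, runs the shared LIF engine, and re-emits
unit-amplitude output trains — the next layer's weights supply amplitudes.

Conventions (bit-exact contracts):

* convolution uses the cross-correlation orientation (no kernel flip), the
  deep-learning convention the converted weights come from;
* "same" padding pads with empty (zero) spike trains;
* flatten is row-major over (H, W, C);
* max-pool forwards, per window, the member train with the largest event
  count unchanged; ties break by row-major first occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .coding import RateCode, encode_spike_steps
from .errors import ShapeError, ValidationError
from .neuron import LIFParams, SimGrid, SpikeTrain, _simulate_drive

__all__ = [
    "SpikeTensor",
    "LayerSpec",
    "encode_tensor",
    "snn_dense",
    "snn_conv2d",
    "snn_maxpool2d",
    "snn_flatten",
    "ann_forward",
]


@dataclass
class SpikeTensor:
    """An array of spike trains sharing one grid.

    ``spikes`` has shape ``shape + (n_steps,)``; layer outputs hold 0/1
    entries (unit amplitudes, at most one event per step).
    """

    spikes: np.ndarray
    grid: SimGrid

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes, dtype=float)
        if self.spikes.shape[-1] != self.grid.n_steps:
            raise ShapeError(
                f"last axis ({self.spikes.shape[-1]}) must equal grid steps "
                f"({self.grid.n_steps})"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.spikes.shape[:-1]

    def counts(self) -> np.ndarray:
        """Event count per train over the window."""
        return np.count_nonzero(self.spikes, axis=-1)

    def frequencies(self) -> np.ndarray:
        """Decoded rate per train: count / T_w, in Hz."""
        return self.counts() / self.grid.t_window

    def train(self, index) -> SpikeTrain:
        """Extract one member as an inspectable :class:`SpikeTrain`."""
        row = self.spikes[index]
        if row.ndim != 1:
            raise ShapeError(f"index {index!r} does not address a single train")
        steps = np.flatnonzero(row)
        return SpikeTrain.from_steps(steps, self.grid, row[steps])

    def reshape(self, shape) -> "SpikeTensor":
        return SpikeTensor(
            self.spikes.reshape(tuple(shape) + (self.grid.n_steps,)), self.grid
        )


def encode_tensor(x: np.ndarray, code: RateCode) -> SpikeTensor:
    """Rate-encode every element of ``x`` (values in [0, 1])."""
    x = np.asarray(x, dtype=float)
    out = np.zeros(x.shape + (code.grid.n_steps,))
    for idx in np.ndindex(*x.shape):
        out[idx][encode_spike_steps(x[idx], code)] = 1.0
    return SpikeTensor(out, code.grid)


@dataclass
class LayerSpec:
    """One layer of a (convertible) network.

    ``weights``: dense ``(out, in)``; conv2d ``(kh, kw, c_in, c_out)``.
    ``lif`` holds the layer's spiking-side parameters after conversion
    (``gl`` may be per-unit, see :mod:`spikemap.network`).
    """

    kind: str
    weights: np.ndarray | None = None
    bias: np.ndarray | None = None
    slope: float = 1.0
    stride: int = 1
    padding: int | str = 0
    pool: tuple[int, int] | None = None
    lif: LIFParams | None = None
    gl_per_unit: np.ndarray | None = None

    KINDS = ("dense", "conv2d", "maxpool2d", "flatten")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValidationError(f"unknown layer kind {self.kind!r}")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
        if self.bias is not None:
            self.bias = np.asarray(self.bias, dtype=float)
        if self.stride < 1:
            raise ValidationError(f"stride must be >= 1, got {self.stride}")

    # -- constructors -------------------------------------------------------
    @staticmethod
    def dense(weights, bias=None, slope: float = 1.0) -> "LayerSpec":
        w = np.asarray(weights, dtype=float)
        if w.ndim != 2:
            raise ValidationError("dense weights must be 2-D (out, in)")
        b = np.zeros(w.shape[0]) if bias is None else np.asarray(bias, float)
        if b.shape != (w.shape[0],):
            raise ValidationError("dense bias must have one entry per output")
        return LayerSpec("dense", weights=w, bias=b, slope=slope)

    @staticmethod
    def conv2d(
        weights, bias=None, slope: float = 1.0, stride: int = 1,
        padding: int | str = "same",
    ) -> "LayerSpec":
        w = np.asarray(weights, dtype=float)
        if w.ndim != 4:
            raise ValidationError("conv2d weights must be 4-D (kh, kw, c_in, c_out)")
        b = np.zeros(w.shape[3]) if bias is None else np.asarray(bias, float)
        if b.shape != (w.shape[3],):
            raise ValidationError("conv2d bias must have one entry per channel")
        if padding == "same" and (w.shape[0] != w.shape[1] or w.shape[0] % 2 == 0):
            raise ValidationError('"same" padding needs an odd square kernel')
        return LayerSpec(
            "conv2d", weights=w, bias=b, slope=slope, stride=stride,
            padding=padding,
        )

    @staticmethod
    def maxpool2d(window: tuple[int, int] | int, stride: int | None = None) -> "LayerSpec":
        win = (window, window) if isinstance(window, int) else tuple(window)
        return LayerSpec("maxpool2d", pool=win, stride=stride or win[0])

    @staticmethod
    def flatten() -> "LayerSpec":
        return LayerSpec("flatten")

    # -- shape algebra ------------------------------------------------------
    def _pad_amount(self) -> int:
        if self.padding == "same":
            kh, kw = self.weights.shape[:2]
            if kh != kw or kh % 2 == 0:
                raise ValidationError('"same" padding needs an odd square kernel')
            return (kh - 1) // 2
        return int(self.padding)

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        """Output shape for ``in_shape``; raises :class:`ValidationError`."""
        if self.kind == "dense":
            if len(in_shape) != 1 or in_shape[0] != self.weights.shape[1]:
                raise ValidationError(
                    f"dense weights {self.weights.shape} incompatible with "
                    f"input shape {in_shape}"
                )
            return (self.weights.shape[0],)
        if self.kind == "conv2d":
            if len(in_shape) != 3 or in_shape[2] != self.weights.shape[2]:
                raise ValidationError(
                    f"conv2d filter {self.weights.shape} incompatible with "
                    f"input shape {in_shape}"
                )
            kh, kw = self.weights.shape[:2]
            p = self._pad_amount()
            h = (in_shape[0] + 2 * p - kh) // self.stride + 1
            w = (in_shape[1] + 2 * p - kw) // self.stride + 1
            if h < 1 or w < 1:
                raise ValidationError("conv2d kernel larger than padded input")
            return (h, w, self.weights.shape[3])
        if self.kind == "maxpool2d":
            if len(in_shape) != 3:
                raise ValidationError("maxpool2d expects (H, W, C) input")
            ph, pw = self.pool
            h = (in_shape[0] - ph) // self.stride + 1
            w = (in_shape[1] - pw) // self.stride + 1
            if h < 1 or w < 1:
                raise ValidationError("pool window does not fit the input")
            return (h, w, in_shape[2])
        return (int(np.prod(in_shape)),)  # flatten


def _layer_lif(spec: LayerSpec) -> LIFParams:
    return spec.lif if spec.lif is not None else LIFParams()


def _run_engine(
    drive: np.ndarray, spec: LayerSpec, gl: np.ndarray | float | None, grid: SimGrid
) -> np.ndarray:
    lif = _layer_lif(spec)
    if gl is None:
        gl = spec.gl_per_unit if spec.gl_per_unit is not None else lif.gl
    _, _, s = _simulate_drive(
        drive, lif.cm, gl, lif.v_th, lif.reset_mode, grid.dt,
        v_reset=lif.v_reset, v_rest=lif.v_rest,
    )
    return s.astype(float)


def snn_dense(
    inp: SpikeTensor, spec: LayerSpec, gl: np.ndarray | None = None
) -> SpikeTensor:
    """Fully connected spiking layer: weight rows become drive amplitudes."""
    if len(inp.shape) != 1 or inp.shape[0] != spec.weights.shape[1]:
        raise ShapeError(
            f"dense weights {spec.weights.shape} incompatible with input "
            f"shape {inp.shape}"
        )
    drive = spec.weights @ inp.spikes
    return SpikeTensor(_run_engine(drive, spec, gl, inp.grid), inp.grid)


def snn_conv2d(
    inp: SpikeTensor, spec: LayerSpec, gl: np.ndarray | None = None
) -> SpikeTensor:
    """Spiking 2-D convolution (cross-correlation orientation).

    Padding contributes empty spike trains; each output unit's drive is the
    receptive-field superposition weighted by the filter entries.
    """
    if len(inp.shape) != 3 or inp.shape[2] != spec.weights.shape[2]:
        raise ShapeError(
            f"conv2d filter {spec.weights.shape} incompatible with input "
            f"shape {inp.shape}"
        )
    kh, kw, _, c_out = spec.weights.shape
    p = spec._pad_amount()
    s = inp.spikes
    if p:
        s = np.pad(s, ((p, p), (p, p), (0, 0), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(s, (kh, kw), axis=(0, 1))
    win = win[:: spec.stride, :: spec.stride]  # (H', W', C, T, kh, kw)
    drive = np.einsum("abctij,ijcd->abdt", win, spec.weights, optimize=True)
    h_out, w_out, _ = drive.shape[:3]
    flat = drive.reshape(h_out * w_out * c_out, -1)
    if gl is None and spec.gl_per_unit is not None:
        gl = spec.gl_per_unit
    if gl is not None:
        gl = np.broadcast_to(
            np.asarray(gl, float), (h_out, w_out, c_out)
        ).reshape(-1)
    spikes = _run_engine(flat, spec, gl, inp.grid)
    return SpikeTensor(
        spikes.reshape(h_out, w_out, c_out, inp.grid.n_steps), inp.grid
    )


def snn_maxpool2d(inp: SpikeTensor, spec: LayerSpec) -> SpikeTensor:
    """Forward, per pooling window, the train with the most events.

    Selection only — the forwarded train's timing is untouched.  Ties break
    by row-major first occurrence within the window.
    """
    if len(inp.shape) != 3:
        raise ShapeError("maxpool2d expects an (H, W, C) spike tensor")
    ph, pw = spec.pool
    st = spec.stride
    counts = inp.counts()  # (H, W, C)
    win = np.lib.stride_tricks.sliding_window_view(counts, (ph, pw), axis=(0, 1))
    win = win[::st, ::st]  # (H', W', C, ph, pw)
    h_out, w_out, c = win.shape[:3]
    flatwin = win.reshape(h_out, w_out, c, ph * pw)
    arg = flatwin.argmax(axis=-1)  # row-major first occurrence on ties
    di, dj = np.unravel_index(arg, (ph, pw))
    ii = (np.arange(h_out) * st)[:, None, None] + di
    jj = (np.arange(w_out) * st)[None, :, None] + dj
    cc = np.broadcast_to(np.arange(c)[None, None, :], arg.shape)
    return SpikeTensor(inp.spikes[ii, jj, cc], inp.grid)


def snn_flatten(inp: SpikeTensor) -> SpikeTensor:
    """Row-major reshape of the spike tensor to a vector of trains."""
    return inp.reshape((int(np.prod(inp.shape)),))


def ann_forward(x: np.ndarray, spec: LayerSpec) -> np.ndarray:
    """Reference real-valued forward pass of one layer.

    Dense/conv: ``y = slope * max(0, W.x + b)``; maxpool: windowed max;
    flatten: row-major reshape.
    """
    x = np.asarray(x, dtype=float)
    if spec.kind == "dense":
        if x.shape != (spec.weights.shape[1],):
            raise ShapeError(
                f"dense weights {spec.weights.shape} incompatible with {x.shape}"
            )
        return spec.slope * np.maximum(0.0, spec.weights @ x + spec.bias)
    if spec.kind == "conv2d":
        if x.ndim != 3 or x.shape[2] != spec.weights.shape[2]:
            raise ShapeError(
                f"conv2d filter {spec.weights.shape} incompatible with {x.shape}"
            )
        kh, kw = spec.weights.shape[:2]
        p = spec._pad_amount()
        if p:
            x = np.pad(x, ((p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(0, 1))
        win = win[:: spec.stride, :: spec.stride]  # (H', W', C, kh, kw)
        y = np.einsum("abcij,ijcd->abd", win, spec.weights, optimize=True)
        return spec.slope * np.maximum(0.0, y + spec.bias)
    if spec.kind == "maxpool2d":
        if x.ndim != 3:
            raise ShapeError("maxpool2d expects (H, W, C)")
        ph, pw = spec.pool
        win = np.lib.stride_tricks.sliding_window_view(x, (ph, pw), axis=(0, 1))
        return win[:: spec.stride, :: spec.stride].max(axis=(-2, -1))
    return x.reshape(-1)  # flatten, row-major
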