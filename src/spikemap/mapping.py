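"""Parameter mapping between ReLU artificial neurons and soft-reset LIF neurons.

A ReLU unit ``y = k * max(0, sum_i w_i x_i + b)`` corresponds, under rate
coding, to a linear-reset LIF neuron driven by trains of frequency
``f_i = x_i`` with amplitudes ``w_i``:

* weights pass through unchanged (they become spike amplitudes);
* the activation slope maps to the threshold-capacitance product,
  ``k = 1 / (Vth * Cm)`` — each output spike accounts for ``Vth * Cm`` of
  injected charge, so the leak-free output rate is ``k * sum_i w_i f_i``;
* a non-positive bias maps to the leak conductance ``gl``: the leak makes
  low-frequency inputs unable to reach threshold, exactly as a negative
  bias suppresses small pre-activations.

Three bias conventions are exposed (``MappingConfig.bias_convention``):

``"zero-crossing"`` (default)
    ``b = S * gl / (Cm * ln(1 - S / (Vth * Cm)))`` with ``S = sum(w)``.
    The ReLU's zero crossing ``-b/S`` then equals the *exact* minimum
    firing frequency of the neuron (infinite-window limit).  This is the
    self-consistent convention and reproduces the pairing b = -2.164 <->
    gl = 3 for w = [0.3, 0.2], Vth = Cm = 1.
``"table"``
    ``b = S * gl * ln(1 - S / (Vth * Cm)) / Cm`` — the magnitude of the
    first-order (small 1/(f*tau_m)) approximation, sign fixed to be
    non-positive; gives |b| = 1.04 for the same parameters.
``"steady-state"``
    ``b = -gl * Vth / 2`` — the intercept of the long-run firing-rate
    asymptote: at steady firing the time-averaged membrane potential is
    Vth/2, so the sustained output rate is ``k * (S*f - gl*Vth/2)``.

All three satisfy ``b = 0 <=> gl = 0`` and round-trip exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    InvalidParameterError,
    MappingDomainError,
    UnsupportedBiasError,
)
from .neuron import LIFParams, SimGrid, SpikeTrain, simulate

__all__ = [
    "ReLUParams",
    "MappingConfig",
    "RatePrediction",
    "relu_to_lif",
    "lif_to_relu",
    "min_firing_frequency",
    "min_firing_frequency_simulated",
    "predicted_output_frequency",
    "mapping_report",
]

BIAS_CONVENTIONS = ("zero-crossing", "table", "steady-state")


@dataclass(frozen=True)
class ReLUParams:
    """Artificial-neuron parameters: output contract y = k*max(0, w.x + b)."""

    weights: np.ndarray
    bias: float = 0.0
    slope: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "weights", np.atleast_1d(np.asarray(self.weights, dtype=float))
        )
        if not self.slope > 0:
            raise InvalidParameterError(f"slope must be positive, got {self.slope}")

    @property
    def weight_sum(self) -> float:
        return float(self.weights.sum())

    def output(self, x: np.ndarray | float) -> float:
        """Evaluate the ReLU response for the given per-input values."""
        x = np.broadcast_to(np.asarray(x, dtype=float), self.weights.shape)
        return self.slope * max(0.0, float(self.weights @ x) + self.bias)


@dataclass(frozen=True)
class MappingConfig:
    """Choices fixed on the LIF side of the mapping."""

    v_th: float = 1.0
    t_window: float = 3.0
    bias_convention: str = "zero-crossing"

    def __post_init__(self) -> None:
        if not self.v_th > 0:
            raise InvalidParameterError(f"Vth must be positive, got {self.v_th}")
        if self.bias_convention not in BIAS_CONVENTIONS:
            raise InvalidParameterError(
                f"bias_convention must be one of {BIAS_CONVENTIONS}"
            )


def _log_term(weight_sum: float, v_th: float, cm: float) -> float:
    """ln(1 - S/(Vth*Cm)); the mapping of a bias needs 0 < S < Vth*Cm."""
    ratio = weight_sum / (v_th * cm)
    if not 0 < ratio < 1:
        raise MappingDomainError(
            f"bias mapping requires 0 < sum(weights)={weight_sum:.6g} "
            f"< Vth*Cm={v_th * cm:.6g}"
        )
    return float(np.log1p(-ratio))


def _bias_from_gl(
    gl: float, weight_sum: float, v_th: float, cm: float, convention: str
) -> float:
    if gl == 0:
        return 0.0
    if convention == "steady-state":
        return -gl * v_th / 2.0
    log_term = _log_term(weight_sum, v_th, cm)  # negative
    if convention == "zero-crossing":
        return weight_sum * gl / (cm * log_term)
    return weight_sum * gl * log_term / cm  # "table"


def _gl_from_bias(
    bias: float, weight_sum: float, v_th: float, cm: float, convention: str
) -> float:
    if bias == 0:
        return 0.0
    if bias > 0:
        raise UnsupportedBiasError(
            f"positive bias ({bias}) has no leak counterpart; only b <= 0 maps"
        )
    if convention == "steady-state":
        return -2.0 * bias / v_th
    log_term = _log_term(weight_sum, v_th, cm)
    if convention == "zero-crossing":
        return bias * cm * log_term / weight_sum
    return bias * cm / (weight_sum * log_term)  # "table"


def relu_to_lif(relu: ReLUParams, cfg: MappingConfig = MappingConfig()) -> LIFParams:
    """Map a ReLU unit to an equivalent linear-reset LIF neuron.

    ``Cm = 1/(k*Vth)``; ``gl`` solves the bias relation of the configured
    convention.  Weights pass through unchanged (they live on the synapses,
    not in the neuron).
    """
    cm = 1.0 / (relu.slope * cfg.v_th)
    gl = _gl_from_bias(
        relu.bias, relu.weight_sum, cfg.v_th, cm, cfg.bias_convention
    )
    return LIFParams(cm=cm, gl=gl, v_th=cfg.v_th, reset_mode="linear")


def lif_to_relu(
    params: LIFParams,
    weights: np.ndarray | list[float],
    cfg: MappingConfig = MappingConfig(),
) -> ReLUParams:
    """Inverse mapping; round-trips with :func:`relu_to_lif` to 1e-9."""
    if params.reset_mode != "linear":
        raise MappingDomainError("only linear (soft) reset neurons map to ReLU")
    weights = np.atleast_1d(np.asarray(weights, dtype=float))
    k = 1.0 / (params.v_th * params.cm)
    b = _bias_from_gl(
        params.gl, float(weights.sum()), params.v_th, params.cm,
        cfg.bias_convention,
    )
    return ReLUParams(weights=weights, bias=b, slope=k)


def min_firing_frequency(
    params: LIFParams, weights: np.ndarray | list[float], t_window: float
) -> float:
    """Smallest equal input frequency that fires within the window.

    Derived by inverting the closed-form potential at the window horizon:
    with ``A = (S/(Vth*Cm)) * (1 - exp(-T_w/tau_m))``,

        f_min = -1 / (tau_m * ln(1 - A)),

    and the leak-free limit ``Vth*Cm / (S * T_w)`` (the first spike needs
    ``ceil(Vth*Cm/S)`` inputs to arrive inside the window).
    """
    if params.reset_mode != "linear":
        raise MappingDomainError("min firing frequency is defined for linear reset")
    s = float(np.sum(weights))
    if not s > 0:
        raise MappingDomainError(f"sum(weights) must be positive, got {s}")
    if not t_window > 0:
        raise InvalidParameterError(f"t_window must be positive, got {t_window}")
    if params.gl == 0:
        return params.v_th * params.cm / (s * t_window)
    tau = params.tau_m
    a = s / (params.v_th * params.cm) * (1.0 - np.exp(-t_window / tau))
    if a >= 1:
        raise MappingDomainError(
            "precondition sum(w)*(1-exp(-T_w/tau_m)) < Vth*Cm violated"
        )
    return float(-1.0 / (tau * np.log1p(-a)))


def _fires(f: float, params: LIFParams, weights_sum: float, grid: SimGrid) -> bool:
    """Does a superposed equal-frequency input at ``f`` Hz fire within T_w?"""
    n = int(np.floor(grid.t_window * f + 1e-9))
    if n == 0:
        return False
    times = np.arange(1, n + 1) / f
    idx = np.clip(
        np.floor(times / grid.dt + 0.5 - 1e-12).astype(int) - 1,
        0,
        grid.n_steps - 1,
    )
    train = SpikeTrain.from_steps(idx, grid, weights_sum)
    return simulate(train, params, grid).n_spikes > 0


def min_firing_frequency_simulated(
    params: LIFParams,
    weights: np.ndarray | list[float],
    grid: SimGrid,
    f_hi: float = 200.0,
    resolution: float = 1e-3,
) -> float:
    """Bisection on the grid simulator; companion oracle for the analytic
    formula.  Returns the smallest firing frequency to ``resolution`` Hz."""
    s = float(np.sum(weights))
    lo, hi = 0.0, None
    f = max(min_firing_frequency(params, weights, grid.t_window), 1.0 / grid.t_window)
    while f <= f_hi:
        if _fires(f, params, s, grid):
            hi = f
            break
        lo = f
        f *= 2.0
    if hi is None:
        raise MappingDomainError(f"neuron never fires below {f_hi} Hz")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if _fires(mid, params, s, grid):
            hi = mid
        else:
            lo = mid
    return hi


@dataclass(frozen=True)
class RatePrediction:
    """Named analytic predictions of the output spike frequency.

    ``first_crossing``: equal-frequency law f_o = f_in / n*, where n* is the
    smallest spike count whose closed-form potential reaches Vth.  Exact for
    the *time of the first* output spike; the soft reset retains surplus, so
    the long-run rate can exceed it.  ``None`` for unequal input rates,
    0.0 if the neuron can never reach threshold.

    ``proportional``: first-order law f_o = sum_i(w_i f_i) / (Vth * Cm) — the
    ReLU-equivalent long-run rate (exact for gl = 0 up to 1/T quantisation).
    """

    first_crossing: float | None
    proportional: float


def predicted_output_frequency(
    f_in: np.ndarray | list[float] | float,
    weights: np.ndarray | list[float],
    params: LIFParams,
    max_n: int = 100_000,
) -> RatePrediction:
    weights = np.atleast_1d(np.asarray(weights, dtype=float))
    f_in = np.broadcast_to(np.asarray(f_in, dtype=float), weights.shape)
    proportional = float(weights @ f_in) / (params.v_th * params.cm)
    first = None
    if f_in.size and np.all(f_in == f_in[0]) and f_in[0] > 0:
        f = float(f_in[0])
        s = float(weights.sum())
        first = 0.0
        if s > 0:
            if params.gl > 0:
                r = np.exp(-1.0 / (f * params.tau_m))
                limit = s / params.cm / (1.0 - r)
                reachable = limit >= params.v_th - 1e-12
            else:
                reachable = True
            if reachable:
                n_star = None
                for n in range(1, max_n + 1):
                    v = (
                        n * s / params.cm
                        if params.gl == 0
                        else s / params.cm * (1.0 - r**n) / (1.0 - r)
                    )
                    if v >= params.v_th - 1e-12:
                        n_star = n
                        break
                first = f / n_star if n_star else 0.0
    return RatePrediction(first_crossing=first, proportional=proportional)


def mapping_report(
    relu: ReLUParams, cfg: MappingConfig = MappingConfig()
) -> dict:
    """JSON-ready account of one unit's mapping: parameters both ways,
    validity flags and the minimum firing frequency (analytic)."""
    report: dict = {
        "relu": {
            "weights": relu.weights.tolist(),
            "bias": relu.bias,
            "slope": relu.slope,
        },
        "config": {
            "v_th": cfg.v_th,
            "t_window": cfg.t_window,
            "bias_convention": cfg.bias_convention,
        },
    }
    cm = 1.0 / (relu.slope * cfg.v_th)
    s = relu.weight_sum
    report["validity"] = {
        "weight_sum": s,
        "bias_mapping_valid": bool(0 < s < cfg.v_th * cm) or relu.bias == 0,
        "bias_nonpositive": relu.bias <= 0,
    }
    try:
        lif = relu_to_lif(relu, cfg)
    except MappingDomainError as exc:
        report["error"] = str(exc)
        return report
    report["lif"] = {
        "cm": lif.cm,
        "gl": lif.gl,
        "v_th": lif.v_th,
        "reset_mode": lif.reset_mode,
    }
    if s > 0:
        report["f_min_analytic"] = min_firing_frequency(
            lif, relu.weights, cfg.t_window
        )
        report["relu_zero_crossing"] = -relu.bias / s if s else None
    back = lif_to_relu(lif, relu.weights, cfg)
    report["round_trip"] = {"bias": back.bias, "slope": back.slope}
    return report
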