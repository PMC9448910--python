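"""Equivalence quantification between a spiking network and its ReLU source.

Correlation uses the Pearson product-moment form

    rho = (n*Sxy - Sx*Sy) / sqrt((n*Sxx - Sx^2) * (n*Syy - Sy^2)),

computed from raw sums exactly as written; units that are silent on every
input have zero variance, make rho undefined, and are excluded (and
reported) rather than silently dropped.

The coding-time error bound: a decoded rate is a count over a window ``T``,
so it differs from the intended rate by less than ``1/T``; deep cascades
compound the per-layer bound, so exceedances are flagged, not fatal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import RangeError, ShapeError, UndefinedCorrelationError

__all__ = [
    "correlation",
    "correlation_matrices",
    "agreement",
    "frequency_error_report",
    "FrequencyErrorReport",
    "EquivalenceReport",
]


def correlation(x, y) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.size != y.size or x.size < 2:
        raise ShapeError("correlation needs two equal-length vectors (n >= 2)")
    n = x.size
    sx, sy = x.sum(), y.sum()
    vx = n * (x @ x) - sx * sx
    vy = n * (y @ y) - sy * sy
    if vx <= 0 or vy <= 0:
        raise UndefinedCorrelationError(
            "correlation undefined: an input has zero variance"
        )
    return float((n * (x @ y) - sx * sy) / np.sqrt(vx * vy))


def correlation_matrices(
    snn_outputs: np.ndarray, ann_outputs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cross-model correlation matrices along the data and neuron dimensions.

    Inputs are ``(n_data, n_neurons)`` matrices of matched outputs.  The
    data-dimension matrix correlates all ``2*n_data`` per-datum output
    vectors (ANN rows first, then SNN rows: the diagonal blocks are
    within-model, the off-diagonal blocks cross-model).  The
    neuron-dimension matrix does the same for per-neuron vectors after
    dropping neurons with zero variance in either model; the dropped
    indices are returned.
    """
    snn = np.asarray(snn_outputs, dtype=float)
    ann = np.asarray(ann_outputs, dtype=float)
    if snn.shape != ann.shape or snn.ndim != 2:
        raise ShapeError(f"matched (n_data, n_neurons) matrices required, "
                         f"got {snn.shape} and {ann.shape}")
    data_mat = np.corrcoef(np.vstack([ann, snn]))
    var_ok = (ann.var(axis=0) > 0) & (snn.var(axis=0) > 0)
    excluded = np.flatnonzero(~var_ok)
    neuron_mat = np.corrcoef(
        np.vstack([ann[:, var_ok].T, snn[:, var_ok].T])
    )
    return data_mat, neuron_mat, excluded


def agreement(
    labels_a, labels_b, n_classes: int
) -> tuple[np.ndarray, float]:
    """Confusion matrix (rows: reference ``labels_a``; columns: ``labels_b``)
    and the agreement rate trace/total."""
    a = np.asarray(labels_a, dtype=int).reshape(-1)
    b = np.asarray(labels_b, dtype=int).reshape(-1)
    if a.size != b.size:
        raise ShapeError("label vectors must have equal length")
    if a.size == 0:
        raise ShapeError("label vectors must be non-empty")
    if a.min() < 0 or b.min() < 0 or a.max() >= n_classes or b.max() >= n_classes:
        raise RangeError(f"labels must lie in [0, {n_classes})")
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(confusion, (a, b), 1)
    rate = float(np.trace(confusion)) / a.size
    return confusion, rate


@dataclass
class FrequencyErrorReport:
    """Per-unit decoded-frequency errors against the 1/T coding bound."""

    errors: np.ndarray
    max_error: float
    bound: float
    exceeding: np.ndarray  # indices beyond the single-stage bound (flagged)
    t_window: float

    def max_error_percent(self, f_max: float) -> float:
        """Max error as a percentage of the maximum coding frequency."""
        return 100.0 * self.max_error / f_max

    def to_dict(self) -> dict:
        return {
            "errors_hz": self.errors.tolist(),
            "max_error_hz": self.max_error,
            "bound_hz": self.bound,
            "exceeding_indices": self.exceeding.tolist(),
            "t_window_s": self.t_window,
        }


def frequency_error_report(
    snn_frequencies, ann_frequencies, t_window: float
) -> FrequencyErrorReport:
    """Absolute per-unit errors |f_snn - f_ann|, their max, and the 1/T bound."""
    f_snn = np.asarray(snn_frequencies, dtype=float).reshape(-1)
    f_ann = np.asarray(ann_frequencies, dtype=float).reshape(-1)
    if f_snn.shape != f_ann.shape:
        raise ShapeError("frequency vectors must have matching length")
    errors = np.abs(f_snn - f_ann)
    bound = 1.0 / t_window
    return FrequencyErrorReport(
        errors=errors,
        max_error=float(errors.max(initial=0.0)),
        bound=bound,
        exceeding=np.flatnonzero(errors > bound),
        t_window=t_window,
    )


@dataclass
class EquivalenceReport:
    """Aggregate SNN-vs-ANN comparison for one network and dataset."""

    snn_frequencies: np.ndarray  # (n_data, n_neurons), decoded, Hz
    ann_frequencies: np.ndarray  # matched ANN activations on the Hz scale
    per_datum_rho: np.ndarray
    mean_rho: float
    min_rho: float
    max_abs_error: float
    bound: float
    agreement_rate: float | None
    excluded_neurons: np.ndarray
    t_window: float

    def to_dict(self) -> dict:
        return {
            "per_datum_rho": self.per_datum_rho.tolist(),
            "mean_rho": self.mean_rho,
            "min_rho": self.min_rho,
            "max_abs_error_hz": self.max_abs_error,
            "bound_hz": self.bound,
            "agreement_rate": self.agreement_rate,
            "excluded_neurons": self.excluded_neurons.tolist(),
            "t_window_s": self.t_window,
            "n_data": int(self.snn_frequencies.shape[0]),
            "n_neurons": int(self.snn_frequencies.shape[1]),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def build(
        cls,
        snn_frequencies,
        ann_frequencies,
        t_window: float,
        labels_snn=None,
        labels_ann=None,
        n_classes: int | None = None,
    ) -> "EquivalenceReport":
        snn = np.atleast_2d(np.asarray(snn_frequencies, dtype=float))
        ann = np.atleast_2d(np.asarray(ann_frequencies, dtype=float))
        if snn.shape != ann.shape:
            raise ShapeError("matched frequency matrices required")
        var_ok = (ann.var(axis=0) > 0) & (snn.var(axis=0) > 0)
        rhos = []
        for i in range(snn.shape[0]):
            try:
                rhos.append(correlation(snn[i], ann[i]))
            except UndefinedCorrelationError:
                rhos.append(np.nan)
        rhos = np.asarray(rhos)
        finite = rhos[np.isfinite(rhos)]
        rate = None
        if labels_snn is not None and labels_ann is not None:
            _, rate = agreement(labels_ann, labels_snn, n_classes)
        return cls(
            snn_frequencies=snn,
            ann_frequencies=ann,
            per_datum_rho=rhos,
            mean_rho=float(finite.mean()) if finite.size else float("nan"),
            min_rho=float(finite.min()) if finite.size else float("nan"),
            max_abs_error=float(np.abs(snn - ann).max(initial=0.0)),
            bound=1.0 / t_window,
            agreement_rate=rate,
            excluded_neurons=np.flatnonzero(~var_ok),
            t_window=t_window,
        )
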