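"""Network description I/O, whole-network ANN-to-SNN conversion, inference.

A :class:`NetworkSpec` is an ordered list of layers with an input shape.  On
disk it is a JSON manifest (structure and metadata) plus a sibling ``.npz``
container holding the weight tensors; the round trip is lossless.

:func:`convert` maps every ReLU layer's (weights, bias, slope) to spiking
parameters (weights, per-unit gl, Cm) at a chosen threshold, layer by layer;
:func:`infer` rate-encodes an input, propagates spike tensors through the
spiking layers, and reads out the index of the output unit with the most
spikes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .coding import RateCode
from .errors import FormatError, MappingDomainError, ShapeError, ValidationError
from .layers import (
    LayerSpec,
    SpikeTensor,
    ann_forward,
    encode_tensor,
    snn_conv2d,
    snn_dense,
    snn_flatten,
    snn_maxpool2d,
)
from .mapping import MappingConfig, ReLUParams, relu_to_lif
from .neuron import LIFParams, SimGrid

__all__ = [
    "NetworkSpec",
    "SNNLayer",
    "SNNModel",
    "InferResult",
    "AnnResult",
    "save_spec",
    "load_spec",
    "convert",
    "infer",
    "ann_infer",
]

FORMAT_VERSION = "spikemap-net-1"


@dataclass
class NetworkSpec:
    """Layered ANN description with weight tensors."""

    input_shape: tuple[int, ...]
    layers: list[LayerSpec]
    version: str = FORMAT_VERSION

    def __post_init__(self) -> None:
        self.input_shape = tuple(int(d) for d in np.atleast_1d(self.input_shape))

    def shapes(self) -> list[tuple[int, ...]]:
        """Chained shapes, input first; raises on any inconsistency."""
        shapes = [self.input_shape]
        for i, layer in enumerate(self.layers):
            try:
                shapes.append(layer.out_shape(shapes[-1]))
            except ValidationError as exc:
                raise ValidationError(f"layer {i} ({layer.kind}): {exc}") from exc
        return shapes

    def validate(self) -> None:
        self.shapes()

    @property
    def output_size(self) -> int:
        return int(np.prod(self.shapes()[-1]))


def save_spec(spec: NetworkSpec, path) -> tuple[Path, Path]:
    """Write ``<path>.json`` (manifest) and ``<path>.npz`` (weights)."""
    base = Path(path)
    if base.suffix == ".json":
        base = base.with_suffix("")
    manifest: dict = {
        "version": spec.version,
        "input_shape": list(spec.input_shape),
        "layers": [],
    }
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(spec.layers):
        entry: dict = {"kind": layer.kind, "slope": layer.slope,
                       "stride": layer.stride, "padding": layer.padding,
                       "pool": list(layer.pool) if layer.pool else None}
        if layer.weights is not None:
            arrays[f"w{i}"] = layer.weights
            entry["weights"] = f"w{i}"
        if layer.bias is not None:
            arrays[f"b{i}"] = layer.bias
            entry["bias"] = f"b{i}"
        manifest["layers"].append(entry)
    json_path = base.with_suffix(".json")
    npz_path = base.with_suffix(".npz")
    json_path.write_text(json.dumps(manifest, indent=2))
    np.savez(npz_path, **arrays)
    return json_path, npz_path


def load_spec(path) -> NetworkSpec:
    """Load and validate a saved network description."""
    base = Path(path)
    if base.suffix == ".json":
        base = base.with_suffix("")
    json_path = base.with_suffix(".json")
    npz_path = base.with_suffix(".npz")
    manifest = json.loads(json_path.read_text())
    if manifest.get("version") != FORMAT_VERSION:
        raise FormatError(
            f"unknown format version {manifest.get('version')!r}; "
            f"expected {FORMAT_VERSION!r}"
        )
    arrays = dict(np.load(npz_path)) if npz_path.exists() else {}
    layers = []
    for entry in manifest["layers"]:
        padding = entry.get("padding", 0)
        layers.append(
            LayerSpec(
                kind=entry["kind"],
                weights=arrays.get(entry.get("weights")),
                bias=arrays.get(entry.get("bias")),
                slope=entry.get("slope", 1.0),
                stride=entry.get("stride", 1),
                padding=padding,
                pool=tuple(entry["pool"]) if entry.get("pool") else None,
            )
        )
    spec = NetworkSpec(tuple(manifest["input_shape"]), layers)
    spec.validate()
    return spec


@dataclass
class SNNLayer:
    """A converted spiking layer with per-unit leak conductances.

    ``source_index`` records which ANN layer this one came from.
    """

    spec: LayerSpec
    lif: LIFParams | None = None
    gl: np.ndarray | None = None
    source_index: int = -1


@dataclass
class SNNModel:
    """A converted spiking network plus its simulation/coding configuration."""

    layers: list[SNNLayer]
    grid: SimGrid
    code: RateCode
    input_shape: tuple[int, ...]
    mapping: MappingConfig = field(default_factory=MappingConfig)


def _unit_weight_sums(layer: LayerSpec) -> np.ndarray:
    if layer.kind == "dense":
        return layer.weights.sum(axis=1)
    return layer.weights.sum(axis=(0, 1, 2))  # conv2d: per output channel


def convert(
    spec: NetworkSpec,
    cfg: MappingConfig = MappingConfig(),
    grid: SimGrid | None = None,
    code: RateCode | None = None,
) -> SNNModel:
    """Convert every ReLU layer to a spiking layer via the parameter mapping.

    Each unit keeps its weights, gets ``Cm = 1/(slope * Vth)`` and a leak
    conductance solved from its bias (0 for bias-free units).  Max-pool and
    flatten layers pass through.  A unit whose bias cannot be mapped raises
    :class:`MappingDomainError` naming the layer and unit.
    """
    spec.validate()
    grid = grid or SimGrid()
    code = code or RateCode(grid=grid)
    out_layers: list[SNNLayer] = []
    for i, layer in enumerate(spec.layers):
        if layer.kind in ("maxpool2d", "flatten"):
            out_layers.append(SNNLayer(spec=layer, source_index=i))
            continue
        sums = _unit_weight_sums(layer)
        bias = layer.bias if layer.bias is not None else np.zeros(sums.shape)
        gl = np.zeros(sums.shape)
        lif_ref = None
        for j, (s, b) in enumerate(zip(sums, bias)):
            try:
                lif_j = relu_to_lif(
                    ReLUParams(weights=np.array([s]), bias=float(b),
                               slope=layer.slope),
                    cfg,
                )
            except MappingDomainError as exc:
                raise MappingDomainError(
                    f"layer {i} ({layer.kind}) unit {j}: {exc}"
                ) from exc
            gl[j] = lif_j.gl
            lif_ref = lif_j
        out_layers.append(
            SNNLayer(
                spec=layer,
                lif=LIFParams(cm=lif_ref.cm, gl=0.0, v_th=cfg.v_th,
                              reset_mode="linear"),
                gl=gl,
                source_index=i,
            )
        )
    return SNNModel(out_layers, grid, code, spec.input_shape, cfg)


@dataclass
class InferResult:
    label: int
    layer_outputs: list[SpikeTensor]
    counts: np.ndarray
    silent: bool


@dataclass
class AnnResult:
    label: int
    activations: list[np.ndarray]


def infer(model: SNNModel, x: np.ndarray) -> InferResult:
    """Spike-based inference: encode, propagate, argmax spike count.

    Ties resolve toward the smallest index; an all-silent output layer
    yields label 0 with ``silent=True``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != tuple(model.input_shape):
        raise ShapeError(
            f"input shape {x.shape} != model input shape {model.input_shape}"
        )
    tensor = encode_tensor(x, model.code)
    outputs: list[SpikeTensor] = []
    for snn_layer in model.layers:
        spec = snn_layer.spec
        if spec.kind == "dense":
            spec = replace(spec, lif=snn_layer.lif)
            tensor = snn_dense(tensor, spec, gl=snn_layer.gl)
        elif spec.kind == "conv2d":
            spec = replace(spec, lif=snn_layer.lif)
            tensor = snn_conv2d(tensor, spec, gl=snn_layer.gl)
        elif spec.kind == "maxpool2d":
            tensor = snn_maxpool2d(tensor, spec)
        else:
            tensor = snn_flatten(tensor)
        outputs.append(tensor)
    counts = outputs[-1].counts().reshape(-1)
    label = int(np.argmax(counts))
    return InferResult(label, outputs, counts, silent=bool(counts.max() == 0))


def ann_infer(spec: NetworkSpec, x: np.ndarray) -> AnnResult:
    """Reference real-valued forward pass; label = argmax (ties: smallest)."""
    x = np.asarray(x, dtype=float)
    if x.shape != tuple(spec.input_shape):
        raise ShapeError(
            f"input shape {x.shape} != spec input shape {spec.input_shape}"
        )
    activations: list[np.ndarray] = []
    for layer in spec.layers:
        x = ann_forward(x, layer)
        activations.append(x)
    return AnnResult(int(np.argmax(x.reshape(-1))), activations)
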