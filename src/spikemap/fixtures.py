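"""Seeded synthetic generators: random ReLU networks, images, and a
separable two-class dataset with a hand-constructed reference classifier.

Everything is produced by ``numpy.random.default_rng(seed)`` with a
documented draw order, so the same seed yields bit-identical fixtures on
any platform.  No training happens anywhere: the equivalence claims under
test are about conversion fidelity, not classifier quality, so reference
networks are random or hand-constructed template matchers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .layers import LayerSpec
from .network import NetworkSpec, ann_infer

__all__ = [
    "FixtureConfig",
    "gen_network",
    "gen_images",
    "gen_two_class_dataset",
]

# Architecture descriptor entries:
#   int                      -> dense layer with that many units
#   ("conv2d", c_out, k)     -> k x k conv, "same" padding, stride 1
#   ("maxpool2d", p)         -> p x p max pool, stride p
#   "flatten"                -> row-major flatten
# The first entry is the input: an int (vector) or an (H, W, C) tuple.


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 0
    architecture: tuple = (16, 8, 4)
    weight_scale: float = 0.8  # per-unit sum |w|; keeps biased mapping valid
    bias_fraction: float = 0.0  # fraction of dense units given negative bias
    image_shape: tuple = (10, 10)
    n_classes: int = 2
    v_th: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.weight_scale:
            raise ConfigError("weight_scale must be positive")
        if not 0 <= self.bias_fraction <= 1:
            raise ConfigError("bias_fraction must lie in [0, 1]")


def _scale_rows(w: np.ndarray, scale: float) -> np.ndarray:
    """Rescale each row so sum |w| equals ``scale`` exactly."""
    norms = np.abs(w).sum(axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return w * scale / norms


def gen_network(cfg: FixtureConfig) -> NetworkSpec:
    """Reproducible random bias-free network from the architecture descriptor.

    Dense weights are standard-normal draws rescaled so each unit satisfies
    ``sum |w| = weight_scale`` (with ``weight_scale <= 0.8 * Vth * Cm`` both
    the biased mapping and the first-crossing search stay well conditioned).
    With ``bias_fraction > 0``, the chosen dense units get all-positive
    weights and a negative bias inside the mapping validity domain.

    Draw order per layer: weights first, then (dense only) the bias mask and
    bias magnitudes.
    """
    rng = np.random.default_rng(cfg.seed)
    desc = list(cfg.architecture)
    if not desc:
        raise ConfigError("architecture descriptor is empty")
    head = desc.pop(0)
    in_shape = (head,) if isinstance(head, int) else tuple(head)
    layers: list[LayerSpec] = []
    shape = in_shape
    for item in desc:
        if isinstance(item, int):  # dense
            if len(shape) != 1:
                raise ConfigError(
                    f"dense layer after non-vector shape {shape}; add 'flatten'"
                )
            w = _scale_rows(rng.standard_normal((item, shape[0])),
                            cfg.weight_scale)
            bias = None
            if cfg.bias_fraction > 0:
                mask = rng.random(item) < cfg.bias_fraction
                w[mask] = np.abs(w[mask])  # positive weight sum for validity
                bias = np.where(
                    mask, -rng.uniform(0.05, 0.5, size=item), 0.0
                )
            layers.append(LayerSpec.dense(w, bias=bias))
            shape = (item,)
        elif item == "flatten":
            layers.append(LayerSpec.flatten())
            shape = (int(np.prod(shape)),)
        elif isinstance(item, tuple) and item[0] == "conv2d":
            _, c_out, k = item
            w = rng.standard_normal((k, k, shape[2], c_out))
            w = w * cfg.weight_scale / np.abs(w).sum(axis=(0, 1, 2),
                                                     keepdims=True)
            layers.append(LayerSpec.conv2d(w, padding="same"))
            shape = (shape[0], shape[1], c_out)
        elif isinstance(item, tuple) and item[0] == "maxpool2d":
            p = item[1]
            layers.append(LayerSpec.maxpool2d(p))
            shape = (shape[0] // p, shape[1] // p, shape[2])
        else:
            raise ConfigError(f"unknown architecture entry {item!r}")
    spec = NetworkSpec(in_shape, layers)
    spec.validate()
    return spec


def _blob(shape, center, sigma, amplitude) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amplitude * np.exp(
        -((yy - center[0]) ** 2 + (xx - center[1]) ** 2) / (2 * sigma**2)
    )


def gen_images(cfg: FixtureConfig, n: int = 10) -> np.ndarray:
    """Reproducible synthetic images in [0, 1]: Gaussian blobs and bars.

    Even indices are blobs at random positions; odd indices are oriented
    bars (horizontal or vertical, one pixel wide, blurred edges).
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_shape
    out = np.zeros((n, h, w))
    for i in range(n):
        if i % 2 == 0:
            cy = rng.uniform(1.5, h - 2.5)
            cx = rng.uniform(1.5, w - 2.5)
            sigma = rng.uniform(0.8, 1.6)
            amp = rng.uniform(0.6, 1.0)
            out[i] = _blob((h, w), (cy, cx), sigma, amp)
        else:
            amp = rng.uniform(0.6, 1.0)
            pos = rng.integers(1, (h if rng.random() < 0.5 else w) - 1)
            img = np.zeros((h, w))
            if rng.random() < 0.5:
                img[pos % h, :] = amp
            else:
                img[:, pos % w] = amp
            out[i] = img
        out[i] += rng.normal(0, 0.01, size=(h, w))
    return np.clip(out, 0.0, 1.0)


def _reference_two_class_spec(shape: tuple[int, int]) -> NetworkSpec:
    """Hand-constructed conv+pool+dense template matcher: left vs right.

    A 3x3 mean filter smooths the image, a 2x2 max-pool downsamples, and a
    dense layer scores the left and right halves of the pooled map.
    """
    h, w = shape
    conv_w = np.full((3, 3, 1, 1), 1.0 / 9.0)
    ph, pw = h // 2, w // 2
    left = np.zeros((ph, pw))
    right = np.zeros((ph, pw))
    left[:, : pw // 2] = 1.0
    right[:, pw - pw // 2 :] = 1.0
    dense_w = np.stack([left.reshape(-1), right.reshape(-1)])
    dense_w = dense_w * 0.8 / np.abs(dense_w).sum(axis=1, keepdims=True)
    layers = [
        LayerSpec.conv2d(conv_w, padding="same"),
        LayerSpec.maxpool2d(2),
        LayerSpec.flatten(),
        LayerSpec.dense(dense_w),
    ]
    return NetworkSpec((h, w, 1), layers)


def gen_two_class_dataset(
    cfg: FixtureConfig, n: int = 40
) -> tuple[np.ndarray, np.ndarray, NetworkSpec]:
    """Linearly separable blob images plus a reference classifier.

    Class 0 blobs sit in the left half of the image, class 1 blobs in the
    right half; labels are balanced to within one.  The returned reference
    network classifies its own data at >= 95% without any training.
    """
    if cfg.n_classes != 2:
        raise ConfigError("the two-class dataset requires n_classes == 2")
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_shape
    if h < 6 or w < 6 or h % 2 or w % 2:
        raise ConfigError("image_shape must be even and at least 6x6")
    labels = np.arange(n) % 2
    rng.shuffle(labels)
    images = np.zeros((n, h, w, 1))
    for i, lab in enumerate(labels):
        cy = rng.uniform(h * 0.3, h * 0.7)
        cx = rng.uniform(w * 0.12, w * 0.28) if lab == 0 else rng.uniform(
            w * 0.72, w * 0.88
        )
        sigma = rng.uniform(1.0, 1.5)
        amp = rng.uniform(0.7, 1.0)
        img = _blob((h, w), (cy, cx), sigma, amp)
        img += rng.normal(0, 0.01, size=(h, w))
        images[i, :, :, 0] = np.clip(img, 0.0, 1.0)
    return images, labels, _reference_two_class_spec((h, w))
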