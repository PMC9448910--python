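"""Spiking and reference dense / conv2d / max-pool layers."""

import numpy as np
import pytest

from spikemap import (
    LIFParams,
    LayerSpec,
    RateCode,
    SimGrid,
    ann_forward,
    encode_tensor,
    snn_conv2d,
    snn_dense,
    snn_flatten,
    snn_maxpool2d,
)
from spikemap.errors import ShapeError, ValidationError
from spikemap.layers import SpikeTensor


@pytest.fixture
def grid4():
    return SimGrid(dt=0.01, t_window=4.0)


@pytest.fixture
def code4(grid4):
    return RateCode(f_max=10.0, grid=grid4)


class TestAnnForward:
    def test_dense_benchmark_arithmetic(self):
        spec = LayerSpec.dense(np.array([[0.3, 0.2]]), bias=np.array([-2.16]))
        out = ann_forward(np.array([10.0, 10.0]), spec)
        assert out[0] == pytest.approx(2.84)

    def test_conv_zero_filter(self):
        spec = LayerSpec.conv2d(np.zeros((3, 3, 1, 2)))
        out = ann_forward(np.random.default_rng(0).random((5, 5, 1)), spec)
        assert out.shape == (5, 5, 2)
        assert np.all(out == 0.0)

    def test_maxpool_and_flatten(self):
        x = np.array([[3.0, 1.0], [2.0, 0.0]]).reshape(2, 2, 1)
        out = ann_forward(x, LayerSpec.maxpool2d(2))
        assert out.reshape(-1)[0] == 3.0
        flat = ann_forward(x, LayerSpec.flatten())
        np.testing.assert_array_equal(flat, [3.0, 1.0, 2.0, 0.0])

    def test_conv_cross_correlation_orientation(self):
        # an asymmetric kernel applied without flip: output at (0,0) with
        # "valid"-style padding 0 is sum of x * w elementwise
        x = np.arange(9, dtype=float).reshape(3, 3, 1)
        w = np.zeros((3, 3, 1, 1))
        w[0, 1, 0, 0] = 1.0  # picks the (0,1) neighbour, no flip
        spec = LayerSpec.conv2d(w, padding=0)
        out = ann_forward(x, spec)
        assert out.shape == (1, 1, 1)
        assert out[0, 0, 0] == x[0, 1, 0]

    def test_shape_mismatch(self):
        spec = LayerSpec.dense(np.ones((2, 3)))
        with pytest.raises(ShapeError):
            ann_forward(np.ones(4), spec)


class TestSnnDense:
    def test_zero_weights_silent(self, code4):
        inp = encode_tensor(np.array([0.5, 0.9]), code4)
        out = snn_dense(inp, LayerSpec.dense(np.zeros((3, 2))))
        assert out.shape == (3,)
        assert np.all(out.counts() == 0)

    def test_unit_weight_passthrough_counts(self, code4):
        inp = encode_tensor(np.array([1.0]), code4)
        out = snn_dense(inp, LayerSpec.dense(np.array([[1.0]])))
        assert out.counts()[0] == inp.counts()[0]

    def test_mapped_layer_matches_ann_rates(self, code4):
        """A random bias-free 8->4 dense layer decoded within the coding
        bound (plus the input-encoding stage) of the ANN activation."""
        rng = np.random.default_rng(42)
        w = rng.standard_normal((4, 8))
        w *= 0.8 / np.abs(w).sum(axis=1, keepdims=True)
        x = rng.random(8)
        inp = encode_tensor(x, code4)
        out = snn_dense(inp, LayerSpec.dense(w))
        decoded = out.frequencies()
        ann = ann_forward(x * code4.f_max, LayerSpec.dense(w))
        bound = 2.0 / code4.grid.t_window
        assert np.all(np.abs(decoded - ann) <= bound)

    def test_shape_mismatch(self, code4):
        inp = encode_tensor(np.array([0.5, 0.9]), code4)
        with pytest.raises(ShapeError):
            snn_dense(inp, LayerSpec.dense(np.zeros((3, 5))))


class TestSnnConv2d:
    def test_zero_filter_silent(self, code4):
        inp = encode_tensor(np.full((4, 4, 1), 0.8), code4)
        out = snn_conv2d(inp, LayerSpec.conv2d(np.zeros((3, 3, 1, 2))))
        assert out.shape == (4, 4, 2)
        assert np.all(out.counts() == 0)

    def test_identity_filter_passthrough(self, code4):
        inp = encode_tensor(np.array([[[0.7]], [[0.2]]]).reshape(2, 1, 1), code4)
        w = np.ones((1, 1, 1, 1))
        out = snn_conv2d(inp, LayerSpec.conv2d(w, padding=0))
        np.testing.assert_array_equal(out.counts(), inp.counts())

    def test_uniform_patch_matches_ann_center(self):
        """3x3 sum filter on a uniform 5 Hz patch: the centre output decodes
        to ~9*5 Hz, matching the ANN conv+ReLU value."""
        grid = SimGrid(dt=0.01, t_window=4.0)
        code = RateCode(f_max=10.0, grid=grid)
        inp = encode_tensor(np.full((5, 5, 1), 0.5), code)
        w = np.ones((3, 3, 1, 1)) / 9.0  # keep rates below the grid ceiling
        out = snn_conv2d(inp, LayerSpec.conv2d(w, padding="same"))
        ann = ann_forward(
            np.full((5, 5, 1), 5.0), LayerSpec.conv2d(w, padding="same")
        )
        center = out.frequencies()[2, 2, 0]
        assert center == pytest.approx(ann[2, 2, 0], abs=2.0 / grid.t_window)

    def test_drive_linearity_before_threshold(self, code4, rng):
        """Leak-free output counts track the discrete cross-correlation of
        the filter with the per-pixel input counts (conservation: each
        output is within one spike of its accumulated drive)."""
        x = rng.random((5, 5, 2))
        w = rng.random((3, 3, 2, 2)) * 0.05  # non-negative filter
        inp = encode_tensor(x, code4)
        out = snn_conv2d(inp, LayerSpec.conv2d(w, padding="same"))
        counts = inp.counts().astype(float)
        # independent route: real-valued correlation of the count map
        expected = ann_forward(counts, LayerSpec.conv2d(w, padding="same"))
        assert np.all(np.abs(out.counts() - expected) < 1.0)

    def test_channel_mismatch(self, code4):
        inp = encode_tensor(np.full((4, 4, 2), 0.5), code4)
        with pytest.raises(ShapeError):
            snn_conv2d(inp, LayerSpec.conv2d(np.zeros((3, 3, 1, 2))))


class TestSnnMaxPool:
    def _tensor_from_counts(self, count_grid, code):
        x = np.asarray(count_grid, dtype=float)
        x = x / (code.f_max * code.grid.t_window)  # value whose count is N
        return encode_tensor(x, code)

    def test_forwards_largest_count(self, code4):
        inp = self._tensor_from_counts([[[3], [1]], [[2], [0]]], code4)
        out = snn_maxpool2d(inp, LayerSpec.maxpool2d(2))
        assert out.counts()[0, 0, 0] == 3
        np.testing.assert_array_equal(
            out.spikes[0, 0, 0], inp.spikes[0, 0, 0]
        )

    def test_tie_breaks_row_major(self, code4):
        # all-equal counts but distinct timings: the (0,0) member wins
        spikes = np.zeros((2, 2, 1, code4.grid.n_steps))
        for k, (i, j) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
            spikes[i, j, 0, 10 + 5 * k] = 1.0
        inp = SpikeTensor(spikes, code4.grid)
        out = snn_maxpool2d(inp, LayerSpec.maxpool2d(2))
        np.testing.assert_array_equal(out.spikes[0, 0, 0], spikes[0, 0, 0])

    def test_matches_ann_maxpool_on_count_map(self, code4, rng):
        x = rng.random((6, 6, 2))
        inp = encode_tensor(x, code4)
        out = snn_maxpool2d(inp, LayerSpec.maxpool2d(2))
        expected = ann_forward(
            inp.counts().astype(float), LayerSpec.maxpool2d(2)
        )
        np.testing.assert_array_equal(out.counts(), expected)

    def test_selection_never_alters_timing(self, code4, rng):
        x = rng.random((4, 4, 1))
        inp = encode_tensor(x, code4)
        out = snn_maxpool2d(inp, LayerSpec.maxpool2d(2))
        for oi in range(2):
            for oj in range(2):
                window = inp.spikes[
                    2 * oi : 2 * oi + 2, 2 * oj : 2 * oj + 2, 0
                ].reshape(4, -1)
                assert any(
                    np.array_equal(out.spikes[oi, oj, 0], row)
                    for row in window
                )


def test_flatten_row_major_order(code4):
    x = np.arange(8).reshape(2, 2, 2) / 10.0
    inp = encode_tensor(x, code4)
    flat = snn_flatten(inp)
    np.testing.assert_array_equal(
        flat.counts(), inp.counts().reshape(-1)
    )


def test_layer_spec_validation():
    with pytest.raises(ValidationError):
        LayerSpec.dense(np.ones(3))  # not 2-D
    with pytest.raises(ValidationError):
        LayerSpec.conv2d(np.ones((2, 2, 1, 1)), padding="same")  # even kernel
    with pytest.raises(ValidationError):
        LayerSpec("mystery")
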