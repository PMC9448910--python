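"""Single-neuron dynamics: closed form, grid simulation, reset rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikemap import (
    LIFParams,
    SimGrid,
    SpikeTrain,
    apply_reset,
    closed_form_potential,
    simulate,
)
from spikemap.errors import AlignmentError, InvalidParameterError

from conftest import periodic_steps

# Frozen from a brute-force Euler integration at dt = 1e-5 (independent of
# the geometric-sum implementation): Cm=1, gl=3, w=0.5, period=0.1 s, n=3.
EULER_POTENTIAL_N3 = 1.1448108


class TestClosedForm:
    @pytest.mark.parametrize(
        "gl,weight,n,expected",
        [(0.0, 0.5, 1, 0.5), (0.0, 0.5, 4, 2.0)],
    )
    def test_leak_free_accumulation(self, gl, weight, n, expected):
        params = LIFParams(cm=1.0, gl=gl)
        assert closed_form_potential(params, weight, 0.37, n) == pytest.approx(
            expected
        )

    def test_matches_fine_grid_integration(self):
        params = LIFParams(cm=1.0, gl=3.0)
        v = closed_form_potential(params, 0.5, 0.1, 3)
        assert v == pytest.approx(EULER_POTENTIAL_N3, abs=1e-4)

    def test_vanishing_leak_limit(self):
        params = LIFParams(cm=1.0, gl=1e-12)
        v = closed_form_potential(params, 0.5, 0.1, 4)
        assert v == pytest.approx(4 * 0.5, abs=1e-9)

    @pytest.mark.parametrize(
        "kwargs", [dict(cm=-1.0), dict(cm=0.0), dict(gl=-0.1), dict(v_th=0.0)]
    )
    def test_invalid_biophysics_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            LIFParams(**kwargs)

    def test_invalid_call_arguments_rejected(self):
        params = LIFParams()
        with pytest.raises(InvalidParameterError):
            closed_form_potential(params, 0.5, 0.1, 0)
        with pytest.raises(InvalidParameterError):
            closed_form_potential(params, 0.5, -0.1, 2)


class TestApplyReset:
    def test_linear_subtracts_threshold(self):
        params = LIFParams(v_th=2.0)
        assert apply_reset(3.0, True, params) == pytest.approx(1.0)

    def test_zero_jumps_to_reset_potential(self):
        params = LIFParams(v_th=2.0, reset_mode="zero")
        assert apply_reset(3.0, True, params) == 0.0

    def test_no_spike_leaves_potential(self):
        for mode in ("linear", "zero"):
            params = LIFParams(v_th=2.0, reset_mode=mode)
            assert apply_reset(0.8, False, params) == 0.8


class TestSimulate:
    def test_empty_input_is_silent(self, grid):
        trace = simulate(SpikeTrain.empty(grid), LIFParams(), grid)
        assert trace.n_spikes == 0
        assert np.all(trace.potential == 0.0)

    @pytest.mark.parametrize("mode", ["linear", "zero"])
    def test_threshold_amplitude_fires_once_and_resets(self, grid, mode):
        params = LIFParams(cm=2.0, v_th=1.5, reset_mode=mode)
        train = SpikeTrain.from_steps([50], grid, params.v_th * params.cm)
        trace = simulate(train, params, grid)
        assert trace.n_spikes == 1
        assert trace.spikes[50]
        assert trace.potential[50] == pytest.approx(0.0, abs=1e-12)

    def test_leak_free_spike_arithmetic(self):
        grid = SimGrid(dt=0.01, t_window=1.0)
        train = SpikeTrain.from_steps(periodic_steps(10.0, grid), grid, 0.5)
        assert train.n_events == 10
        trace = simulate(train, LIFParams(cm=1.0, gl=0.0, v_th=1.0), grid)
        assert trace.n_spikes == 5
        assert trace.final_potential == pytest.approx(0.0, abs=1e-12)

    def test_surplus_above_twice_threshold_carries_forward(self, grid):
        # one event of amplitude 2.5*Vth: one spike that step, the surplus
        # fires again on the next step, 0.5*Vth remains
        train = SpikeTrain.from_steps([10], grid, 2.5)
        trace = simulate(train, LIFParams(cm=1.0, gl=0.0, v_th=1.0), grid)
        assert trace.spikes[10] and trace.spikes[11]
        assert trace.n_spikes == 2
        assert trace.final_potential == pytest.approx(0.5)

    def test_off_grid_event_rejected(self, grid):
        train = SpikeTrain(np.array([0.0151]), np.array([1.0]), grid)
        with pytest.raises(AlignmentError):
            simulate(train, LIFParams(), grid)

    def test_trace_csv_round_trip(self, grid, tmp_path):
        train = SpikeTrain.from_steps(periodic_steps(5.0, grid), grid, 0.7)
        trace = simulate(train, LIFParams(gl=1.0), grid)
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        assert data.shape == (grid.n_steps, 4)
        np.testing.assert_allclose(data[:, 2], trace.potential)


class TestInvariants:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        amps=st.lists(st.floats(0.05, 2.5), min_size=1, max_size=40),
        v_th=st.floats(0.5, 2.0),
    )
    def test_soft_reset_conservation(self, amps, v_th):
        """gl=0, linear: final V + Vth*N_out == (sum amplitudes)/Cm exactly."""
        grid = SimGrid(dt=0.01, t_window=1.0)
        steps = np.linspace(0, grid.n_steps - 1, len(amps)).astype(int)
        steps = np.unique(steps)
        amps = np.asarray(amps[: len(steps)])
        train = SpikeTrain.from_steps(steps, grid, amps)
        params = LIFParams(cm=1.3, gl=0.0, v_th=v_th)
        trace = simulate(train, params, grid)
        lhs = trace.final_potential + v_th * trace.n_spikes
        assert lhs == pytest.approx(amps.sum() / params.cm, abs=1e-9)

    def test_zero_reset_never_outfires_linear(self, rng):
        grid = SimGrid(dt=0.01, t_window=2.0)
        for _ in range(30):
            w = rng.uniform(0.1, 0.9)
            f = rng.uniform(1, 30)
            gl = rng.uniform(0, 3)
            train = SpikeTrain.from_steps(periodic_steps(f, grid), grid, w)
            lin = simulate(train, LIFParams(gl=gl, reset_mode="linear"), grid)
            zer = simulate(train, LIFParams(gl=gl, reset_mode="zero"), grid)
            assert zer.n_spikes <= lin.n_spikes

    def test_output_count_monotone_in_input_rate(self, rng):
        grid = SimGrid(dt=0.01, t_window=2.0)
        for _ in range(10):
            w = rng.uniform(0.2, 0.9)
            gl = rng.uniform(0, 3)
            params = LIFParams(gl=gl)
            counts = [
                simulate(
                    SpikeTrain.from_steps(periodic_steps(f, grid), grid, w),
                    params,
                    grid,
                ).n_spikes
                for f in range(1, 31, 3)
            ]
            assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_grid_simulation_matches_fine_euler_integration(self):
        """Spike counts agree with a dt=1e-5 brute-force Euler integrator
        on >= 99 of 100 random periodic-input cases."""
        rng = np.random.default_rng(7)
        grid = SimGrid(dt=0.01, t_window=2.0)
        n_cases = 100
        dtf = 1e-5
        nf = int(round(grid.t_window / dtf))
        drive = np.zeros((n_cases, nf), dtype=np.float32)
        cases = []
        for c in range(n_cases):
            w = rng.uniform(0.1, 0.9)
            f = rng.uniform(1, 30)
            gl = rng.uniform(0, 3)
            cases.append((w, f, gl))
            coarse = periodic_steps(f, grid)
            fine = ((coarse + 1) * grid.dt / dtf).round().astype(int) - 1
            np.add.at(drive[c], fine, w)
        gls = np.array([c[2] for c in cases])
        v = np.zeros(n_cases)
        counts = np.zeros(n_cases, dtype=int)
        decay = 1.0 - dtf * gls
        for t in range(nf):
            v *= decay
            col = drive[:, t]
            if col.any():
                v += col
            fired = v >= 1.0 - 1e-9
            if fired.any():
                counts[fired] += 1
                v[fired] -= 1.0
        agree = 0
        for c, (w, f, gl) in enumerate(cases):
            train = SpikeTrain.from_steps(periodic_steps(f, grid), grid, w)
            trace = simulate(train, LIFParams(cm=1.0, gl=gl, v_th=1.0), grid)
            agree += trace.n_spikes == counts[c]
        assert agree >= 99
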