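# Methods

## Membrane model and integration scheme

The neuron is the classic RC-circuit leaky integrator:
`Cm dV/dt + gl (V − V0) = I_inj(t)` with `V0 = Vreset = 0` and
`tau_m = Cm/gl`.  All inputs are Dirac trains, so the solution between
events is a pure exponential decay and each event of amplitude `w` is an
instantaneous step `w/Cm`.  The grid simulator therefore applies, per step
of size `dt`: `V ← V·exp(−dt·gl/Cm)`, then injection of the step's summed
event amplitudes, giving the pre-reset potential `H`; if `H ≥ Vth` one
unit spike is emitted and the neuron resets.  For Dirac inputs this
scheme is *exact* — the only discretisation effect is snapping event
times to the grid (nearest step, ties toward the earlier step), worth at
most `dt/2` of timing error per event.  A brute-force Euler integrator at
`dt = 1e−5` is kept in the test suite as an independent oracle; spike
counts agree on 100/100 random periodic-input cases.

Threshold comparisons use an absolute slack of 1e−9: weighted sums such
as 0.3 + 0.2 accumulate float error, and a neuron that mathematically
reaches `Vth` must fire.  At most one spike is emitted per grid step; if
a pathological amplitude drives `H ≥ 2·Vth`, the linear reset carries the
surplus forward and it fires on subsequent steps (tested).  No refractory
period is modelled.

Two reset rules are implemented.  The **linear (soft) reset** `V ← H −
Vth` conserves injected charge: with `gl = 0`,
`V_final + Vth·N_out = (Σ amplitudes)/Cm` holds to float precision
(property-tested over 1,000 random runs), which is the mechanism behind
the ReLU correspondence.  The **reset-to-zero** rule `V ← Vreset`
discards the surplus; its output counts never exceed the soft-reset
counts and fall strictly behind at high input rates.

## Rate coding

`x ∈ [0, 1]` encodes as a unit-amplitude train at `f = x·f_max`, spikes
at `t_j = j/f` for `j = 1..floor(T_w·f)`, snapped to the grid.  The first
spike sits at `1/f`, not 0, so `x = 0` is the empty train.  Decoding is
`N/T`, giving the quantisation bound `|x·f_max − decoded| ≤ 1/T_w`.
Defaults: `dt = 0.01` s, `f_max = 10` Hz (one period per grid step at
full scale), `T_w = 3` s, all configurable; the single-neuron benchmark
uses `T_w = 4` s and network accuracy runs use up to 10 s.  Encoded
values must already lie in [0, 1]; scaling is the caller's duty.

## The parameter mapping and its bias conventions

`Cm = 1/(k·Vth)` identifies the activation slope with the inverse of the
charge per output spike.  The bias–leak relation requires
`0 < Σw < Vth·Cm` (the log argument must lie in (0, 1)) and `b ≤ 0`;
positive biases have no leak counterpart and are rejected.  Three
conventions are exposed because the quantity "the bias equivalent to a
leak" admits three self-consistent readings:

* **zero-crossing** (default): `−b/Σw` equals the exact minimum firing
  frequency `f_min = −1/(tau_m·ln(1 − Σw/(Vth·Cm)))`.  For
  `w = [0.3, 0.2]`, `gl = 3`, `Cm = Vth = 1` this gives `b = −2.164`.
* **table**: the first-order (small `1/(f·tau_m)`) approximation,
  `|b| = Σw·gl·|ln(1 − Σw/(Vth·Cm))|/Cm = 1.040` for the same parameters,
  sign fixed non-positive.
* **steady-state**: `b = −gl·Vth/2`, the intercept of the long-run rate
  asymptote (see below).

All three satisfy `b = 0 ⇔ gl = 0` and round-trip through the inverse
map to 1e−9 relative.

The minimum firing frequency is obtained by inverting the closed-form
periodic-drive potential at the window horizon: with
`A = (Σw/(Vth·Cm))·(1 − e^(−T_w/tau_m))`, `f_min = −1/(tau_m·ln(1−A))`,
leak-free limit `Vth·Cm/(Σw·T_w)`.  This form was chosen over first-order
approximations because it is the one the simulator reproduces: a
bisection-on-simulator finder is part of the public API and agrees with
the analytic value within `1/T_w` across random parameter draws.  It is
increasing in `gl` and *decreasing* in `Σw` (heavier charge per period
fires at lower rates), diverging as `Σw → 0`.

Two output-rate predictions are returned side by side, because they
answer different questions: the **first-crossing law** `f_o = f_in/n*`
(with `n*` the smallest spike count whose closed-form potential reaches
`Vth`) exactly predicts the time of the *first* output spike, and the
**proportional law** `f_o = Σwᵢfᵢ/(Vth·Cm)` predicts the *long-run* rate
(exact for `gl = 0` up to quantisation).  With a leak the two differ: the
soft reset retains the sub-threshold surplus, so later spikes come faster
than the first.

## The transfer curve near threshold (known limitation)

With a leak, the simulated soft-reset transfer curve is not an affine
function of the input rate.  Measured at the benchmark parameters
(`w = [0.3, 0.2]`, `gl = 3`, `Cm = Vth = 1`, `T_w = 4` s): firing starts
at `f_min = 4.33` Hz, and for `f ≳ 6` Hz the curve equals
`Σw·f − gl·Vth/2` to within `1/T_w` — at sustained firing the membrane
potential sweeps `[0, Vth)` roughly uniformly, so the mean leak current
is `gl·Vth/2`.  No straight line passes within `1/T_w` of every point of
such a curve: a line through the firing onset (the zero-crossing bias,
`b = −2.164`) overshoots the asymptote's intercept (`−1.5`) by a constant
≈ 0.66 Hz.  The acceptance test asserting a uniform `1/T_w` agreement
between the leaky neuron and its zero-crossing ReLU over 1–30 Hz
therefore fails, and is left failing: the exact ReLU equivalence holds in
the leak-free (bias-free) case, where charge conservation makes the
output rate `k·Σwᵢfᵢ` up to quantisation — which is the regime all
network-level results use.  For leaky neurons the package reports the
curve itself (`transfer_curve` experiment) rather than pretending an
affine fit.

## Layers and networks

Spiking layers re-emit unit-amplitude trains; the next layer's weights
supply amplitudes.  Convolution uses the cross-correlation orientation
(no kernel flip) since converted weights come from deep-learning layers;
"same" padding pads with empty trains and requires an odd square kernel.
Flatten is row-major over (H, W, C) and must match the dense weight
layout.  Max-pool integrates each member train's event count over the
window and forwards the highest-count train *unchanged* (selection, not
recomputation); ties break by row-major first occurrence.  The readout is
spike-count argmax with ties toward the smaller index; an all-silent
output layer yields label 0 plus a warning flag.  Softmax output layers
of imported descriptions are replaced by the count readout.

Conversion assigns each unit `Cm = 1/(k·Vth)` and a per-unit `gl` solved
from its bias (0 for bias-free units); maxpool/flatten pass through, and
every spiking layer records the index of the ANN layer it came from.  The
on-disk format is a JSON manifest (kinds, shapes, strides, version tag
`spikemap-net-1`) plus a sibling `.npz` with the weight tensors; the
round trip is bit-exact, and loading validates the layer shape chain,
naming the offending layer.

## Error bounds and metrics

A decoded rate is a count over a window, so each coding stage contributes
at most `1/T` of error; cascaded stages compound (encoder + each spiking
layer), which is why network-level checks use small multiples of `1/T`
and the error report *flags* units beyond the single-stage bound instead
of failing.  Percentage errors are reported relative to `f_max`.  Pearson
correlation is implemented from the product-moment sums and cross-checked
against `numpy.corrcoef`; units with zero variance in either model make
the correlation undefined and are excluded automatically, with the
excluded indices a first-class output.  Correlation matrices are built
along both the data dimension (all per-datum output vectors of both
models; diagonal blocks within-model, off-diagonal cross-model) and the
neuron dimension (after exclusion).

## Synthetic data

The generators emulate desk-scale versions of the experimental inputs:
random dense/conv networks with per-unit `Σ|w|` rescaled to exactly 0.8
(keeping the biased mapping and the first-crossing search
well-conditioned, and output rates below the one-spike-per-step grid
ceiling), Gaussian-blob and bar images in [0, 1], and a linearly
separable two-class blob dataset whose reference classifier is a
hand-constructed conv(3×3 mean) → maxpool(2×2) → dense template matcher
scoring the left vs right half of the pooled map.  No training happens
anywhere: the claims under test concern conversion fidelity, not
classifier quality.  All draws come from `numpy.random.default_rng(seed)`
in a documented order, so fixtures are bit-reproducible across platforms.
What the fixtures do *not* emulate: natural image statistics, trained
weight distributions, class overlap, or deep architectures — so passing
tests demonstrate the conversion's correctness and its quantisation
behaviour, not performance on real datasets.

## Problem sizes and numerical choices

Network checks use 16-8-4 dense networks (20 inputs) and 10×10-image
conv+pool+dense networks (up to 100 inputs) at windows of 1–10 s with
`dt = 0.01` s — sizes chosen so every suite runs in seconds while leaving
the quantisation phenomena under study clearly visible.  Bisection for
the minimum firing frequency brackets upward from the analytic value and
stops at 1e−3 Hz.  Ties in snapping go to the earlier grid step; ties in
argmax readouts and max-pool selection go to the first index — all
documented so spike counts are reproducible bit-exactly.
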