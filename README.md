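# spikemap

Soft-reset leaky integrate-and-fire (LIF) neurons, their exact parameter
mapping onto ReLU artificial neurons, and lossless ANN-to-SNN conversion —
from a single neuron up to converted spiking convolutional networks, with
an equivalence-metrics suite.

## The problem

Spiking neural networks exchange information as timed action potentials
rather than real numbers, which makes them biologically plausible and
event-driven but hard to train.  The most effective route to a working SNN
is to *convert* a trained ReLU network: reuse its weights and replace each
unit with a spiking neuron.  For the conversion to be lossless one needs a
precise correspondence between the two neuron models, not just a
similarity.  `spikemap` implements that correspondence for the
**linear-reset (soft-reset) LIF neuron**: a structural, invertible map
between the biophysical parameters of a spiking neuron and the parameters
of a ReLU unit, together with the rate-coding scheme under which the two
produce the same outputs up to a quantisation bound.

## The model

Membrane dynamics of a point neuron with capacitance `Cm`, leak
conductance `gl = 1/Rm`, resting potential 0:

    Cm dV/dt + gl V = I_inj(t),    tau_m = Cm/gl

Inputs are Dirac spike trains whose amplitudes carry the synaptic weights,
so each event of amplitude `w` steps the potential by `w/Cm` and the decay
between events is exactly exponential (the grid simulator is exact, not an
Euler scheme).  When the pre-reset potential `H(t)` reaches the threshold
`Vth` the neuron emits a unit spike and **subtracts** `Vth` (soft reset),
retaining the surplus — this conserves injected charge, which is what
makes the neuron's output rate track a linear function of its input rates.

Rate coding represents a value `x ∈ [0, 1]` as a periodic train at
`f = x · f_max` inside a window `T_w`; decoding counts spikes, so any
decoded rate is within `1/T_w` of its target (the behavioural error bound).

The parameter mapping for a ReLU unit `y = k · max(0, Σ wᵢxᵢ + b)`:

| ReLU side | LIF side |
|---|---|
| weights `w` | spike-train amplitudes `w` (unchanged) |
| slope `k` | `1/(Vth · Cm)` |
| bias `b ≤ 0` | leak `gl` with `b = Σw · gl / (Cm · ln(1 − Σw/(Vth·Cm)))` |

The bias relation (the default "zero-crossing" convention; two printed
variants are also exposed) makes the ReLU's zero crossing `−b/Σw` equal
the neuron's exact minimum firing frequency
`f_min = −1/(tau_m · ln(1 − Σw/(Vth·Cm)))`: a negative bias and a leak
conductance both silence inputs below a threshold rate.  The mapping is
defined for `0 < Σw < Vth·Cm` and round-trips to 1e-9.

On top of the single neuron the package provides spiking dense,
2-D convolution (cross-correlation orientation, zero-spike padding) and
max-pool layers (forward the window's highest-count train unchanged),
whole-network conversion with per-unit leak conductances, spike-count
argmax readout, and metrics: Pearson correlation and cross-model
correlation matrices, confusion/agreement statistics, and frequency-error
reports against the `1/T` bound.

## Worked example

`python examples/relu_mapping.py` maps the biased unit
`y = max(0, 0.3·x₁ + 0.2·x₂ − 2.164)` onto a spiking neuron and verifies
the threshold frequency three ways:

```
mapped LIF parameters      : Cm=1.000, gl=3.000, Vth=1.0, reset=linear
f_min analytic             : 4.3281 Hz
f_min bisection-on-sim     : 4.2922 Hz
ReLU zero crossing -b/sum w: 4.3281 Hz
round trip (b, k)          : (-2.164043, 1.000000)
```

The analytic minimum firing frequency, the bisection on the grid
simulator, and the ReLU zero crossing agree to within the grid resolution:
the bias *is* the leak, expressed in frequency units.

`python examples/network_conversion.py` converts a conv+pool+dense
template classifier and runs spike-based inference at `T_w = 10` s:

```
SNN/ANN label agreement    : 20/20
hidden-layer mean rho      : 0.9998
max output error           : 0.1470 Hz (bound 1/T = 0.10 Hz)
max error % of f_max       : 1.470 %
```

Every label decision of the converted spiking network matches the ReLU
network, and hidden-layer spike rates correlate with the ReLU activations
at ρ ≈ 1; the worst decoded output rate differs by 0.15 Hz (the single-
stage coding bound is 0.10 Hz — cascaded layers compound it slightly).

The other examples (`single_neuron.py`, `transfer_curve.py`) demonstrate
charge conservation under the soft reset and the ReLU-like frequency
transfer curve; a thin CLI (`spikemap encode|simulate|convert|infer|
compare|fixtures|experiment`) exposes the same operations from the shell.

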