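"""Frequency-transfer curves: ReLU line vs soft-reset vs zero-reset LIF.

Sweeps the common input frequency of two synapses (w = [0.3, 0.2]) with
gl = 3, Cm = Vth = 1 over 1..30 Hz and prints the decoded output rates.
The soft-reset neuron follows a ReLU-like curve (dead zone, then linear
growth at slope sum(w)); the zero-reset neuron falls behind at high rates
because it discards the supra-threshold surplus.
"""

from spikemap import SimGrid
from spikemap.experiments import transfer_point

grid = SimGrid(dt=0.01, t_window=4.0)
print(" f_in   ReLU  soft-reset  zero-reset")
for f in range(2, 31, 4):
    relu, lin, zer = transfer_point(f, [0.3, 0.2], 3.0, 1.0, 1.0, grid)
    print(f"{f:5d} {relu:6.2f} {lin:10.2f} {zer:11.2f}")
# Note the systematic offset between the soft-reset curve and the ReLU
# line whose zero crossing matches the firing onset: the long-run rate
# asymptote has intercept -gl*Vth/2 (mean membrane potential Vth/2),
# while firing starts only at f_min = 4.33 Hz.  The curve is exactly
# ReLU-shaped only in the leak-free (bias-free) case.
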