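"""Convert a conv+pool+dense ReLU network to a spiking network and compare.

Builds the synthetic two-class blob dataset with its hand-constructed
reference classifier, converts the network (all neurons leak-free since
the layers are bias-free), runs spike-based inference at T_w = 10 s, and
reports label agreement, hidden-layer correlation and the frequency-error
statistics against the 1/T coding bound.
"""

import numpy as np

from spikemap import (
    MappingConfig,
    RateCode,
    SimGrid,
    ann_infer,
    convert,
    correlation,
    frequency_error_report,
    infer,
)
from spikemap.fixtures import FixtureConfig, gen_two_class_dataset

images, labels, spec = gen_two_class_dataset(FixtureConfig(seed=8), n=20)
grid = SimGrid(dt=0.01, t_window=10.0)
model = convert(spec, MappingConfig(v_th=1.0), grid, RateCode(10.0, grid))

agree = 0
rhos, snn_out, ann_out = [], [], []
for img in images:
    res = infer(model, img)
    ref = ann_infer(spec, img)
    agree += res.label == ref.label
    hidden_snn = res.layer_outputs[2].frequencies().reshape(-1)
    hidden_ann = ref.activations[2].reshape(-1) * 10.0
    rhos.append(correlation(hidden_snn, hidden_ann))
    snn_out.append(res.counts / grid.t_window)
    ann_out.append(ref.activations[-1].reshape(-1) * 10.0)

report = frequency_error_report(
    np.ravel(snn_out), np.ravel(ann_out), grid.t_window
)
print(f"SNN/ANN label agreement    : {agree}/{len(images)}")
print(f"hidden-layer mean rho      : {np.mean(rhos):.4f}")
print(f"max output error           : {report.max_error:.4f} Hz "
      f"(bound 1/T = {report.bound:.2f} Hz)")
print(f"max error % of f_max       : {report.max_error_percent(10.0):.3f} %")
# The decoded spiking rates track the ReLU activations to within the
# coding bound, so classification decisions transfer without training.
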