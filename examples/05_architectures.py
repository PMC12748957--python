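"""The two classifier architectures and their parameter budgets.

AEPQC: one 8-qubit circuit over the amplitude-embedded 250-feature
window — 112 trainable angles. QCNN: a 4-qubit kernel (K1 or K2) slides
over each channel (window 4, stride 2, four layers, 10 -> 2 features),
and a 6-qubit amplitude-embedding head fuses the 27x2 channel outputs
with 18 more angles.
"""

import numpy as np

from qfnirs import QCNN, ModelSpec, build_aepqc, count_params, fuse

rng = np.random.default_rng(0)

aepqc = build_aepqc()
print(f"AEPQC: {aepqc.n_params} trainable parameters, input length {aepqc.n_inputs},")
print(f"       readout wires {aepqc.readout} (8 qubits, pad 6)")

for kernel in ("K1", "K2"):
    spec = ModelSpec("QCNN", kernel=kernel)
    per_kernel = count_params(ModelSpec("QCNN", kernel=kernel, fusion="avg")) // (4 * 27)
    print(f"QCNN-{kernel}: {count_params(spec)} parameters total "
          f"({per_kernel}/kernel x 27 channels x 4 layers + 18 head), "
          f"temporal chain {spec.layer_lengths}")

# forward pass on one scaled window
model = QCNN(ModelSpec("QCNN", kernel="K1"))
w = model.init_weights(rng)
window = rng.uniform(0, np.pi, size=(27, 10))
scores = model.forward(window, w)
cs = model.channel_scores(window, w)
print(f"\nclass scores (Z-expectations, head fusion): {np.round(scores, 4)}")
print(f"channel scores shape: {cs.shape}; avg fusion gives {np.round(fuse(cs, 'avg'), 4)}")

x = rng.normal(size=250)
print(f"AEPQC scores for a random scaled window: "
      f"{np.round(aepqc.forward(x, aepqc.init_weights(rng)), 4)}")
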