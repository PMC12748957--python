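"""Fusion ablation: classification head vs simple channel fusions.

The QCNN reduces each channel to exactly 2 features, so the per-channel
outputs are already class predictions and the 6-qubit amplitude-embedding
head (c_head) can be replaced by simple columnwise fusions: avg, max, or
amax (largest magnitude, sign kept). The network is trained once per
(kernel, fold, seed) with the head; the simple fusions are evaluated
post hoc on the same logged channel scores, so the comparison shares
upstream weights bit-exactly.

Scaled down (2 subjects, 1 seed, short training) to run in ~1 minute.
"""

from qfnirs import SynthConfig, TrainConfig, run_ablation, simulate_dataset

trials = simulate_dataset(SynthConfig(n_subjects=2, effect_amplitude=3.0, seed=5))
table, _, _ = run_ablation(
    trials,
    kernels=("K1", "K2"),
    seeds=(0,),
    train_config=TrainConfig.for_mode("si", max_epochs=30),
)
print(table)
print("\ncells are mean (SD) validation accuracy in percent across subjects")
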