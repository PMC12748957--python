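# qfnirs

Parameterized-quantum-circuit (PQC) classifiers for detecting fear in
functional near-infrared spectroscopy (fNIRS) signals, for researchers
studying quantum machine learning on small neuroimaging datasets.

fNIRS measures cortical oxyhemoglobin changes (ΔHbO) optically; typical
datasets are tiny (here: 14 subjects, 10 trials of 30 s, 27 channels at
10 Hz, binary fear / non-fear labels from virtual-reality height
exposure), which starves deep networks. PQCs — qubit circuits whose gate
angles are trained like weights — are a candidate for this regime, and
this package implements two such classifiers end to end on a pure-numpy
statevector simulator:

* **AEPQC** — amplitude embedding of the flattened window (25 channels ×
  10 samples → 250 features on 8 qubits, 6 zero pads) into a single
  circuit of U3 layers, IsingXX entanglement and measurement-conditioned
  (deferred-measurement) U3 pooling; **112 trainable angles**.
* **QCNN** — a 4-qubit convolutional kernel (light **K1**: RY+RZ+CNOT
  ring, 2 weights/wire; or **K2**: U3/IsingXX with quantum pooling,
  9 weights/wire + 3 entanglers) slides over each channel with window 4 /
  stride 2, shrinking 10 temporal features to 2 over four layers; the
  27×2 channel outputs are fused by a 6-qubit amplitude-embedding
  classification head (**18 angles**) or by simple `avg`/`max`/`amax`
  reductions.

Around the models: robust scaling `x ↦ arctan((x − Q₂)/(Q₃ − Q₁))` with
per-channel training-fold quartiles, [0, π] remapping for angle
embedding, Pearson-correlation channel pruning, leave-one-subject-out
(LOSO) and subject-dependent splits, full-batch Adam with gated early
stopping over 10 seeds, Wilson-score chance thresholds, occlusion-based
channel importance, and a seeded synthetic ΔHbO generator (double-gamma
hemodynamic responses + heavy outliers) so everything runs with no
external download. Circuit gradients are exact adjoint-mode derivatives,
contract-checked against finite differences. See `docs/methods.md` for
the model details and design decisions.

## Worked example

Train QCNN-K1 by LOSO on a 4-subject synthetic dataset whose fear trials
carry a hemodynamic response 3× the noise floor, 3 seeds
(`examples/06_train_crossval.py`, ~2 min):

```
          mean    sd
subject
S01      85.28  1.71
S02      85.28  1.04
S03      86.94  2.08
S04      86.94  0.39
Mean     86.11  0.83

chance threshold for n=120: 58.95%
mean accuracy 86.11% -> better than chance
```

Per-subject rows are mean (SD) validation accuracy in percent over the
3 weight-initialization seeds; 120 is the number of validation windows
of a held-out subject (10 trials × 12 windows), and 58.95% is the
smallest accuracy whose 95% Wilson-interval lower bound clears 50% — so
the model's performance is statistically distinguishable from guessing.
With the class effect removed the same pipeline stays at chance
(~50%), and occlusion importance on a one-informative-channel dataset
concentrates on that channel (`examples/07_channel_importance.py`):

```
S01: importance sums to 1.000; top channels: ch07=0.758, ch21=0.078, ch14=0.034
S02: importance sums to 1.000; top channels: ch07=0.750, ch01=0.076, ch10=0.067
```

The other examples cover the Wilson thresholds, the generator, the
preprocessing chain (on the default synthetic world the Pearson pruning
drops channels 22 and 24), the circuit core with gradients, the
architecture parameter budgets, and the head-vs-simple-fusion ablation.
Each is a short script: `python examples/01_wilson_thresholds.py` etc.

To run on real recordings instead, lay the data out as one
samples×channels TSV per subject plus a JSON manifest (see
`qfnirs.synth.write_dataset` for the exact format) and pass
`qfnirs.read_dataset(path)` to `run_crossval`.

## Acceptance script

`scripts/acceptance.py` recomputes the two published analytic targets
from scratch — the minimum better-than-chance accuracies for validation
sets of 120 and 48 windows, via the package's Wilson-bound grid scan —
and writes them as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
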