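# Methods

`qfnirs` implements parameterized-quantum-circuit (PQC) classifiers for
binary fear detection in functional near-infrared spectroscopy (fNIRS)
oxyhemoglobin (ΔHbO) signals, together with the full evaluation protocol
and a synthetic data generator. Everything runs on a pure-numpy
statevector simulator written for this package; no quantum-computing
framework is used.

## The simulation core

**State and conventions.** An n-qubit pure state is a complex vector of
2^n amplitudes with unit L2 norm. Qubit 0 is the most significant bit of
the basis index (so reshaping to `(2,)*n` puts qubit k on axis k). All
angles are radians; no reduction modulo 2π is performed (inputs are
constrained to [0, π] before angle embedding).

**Gate set.** U3(θ, φ, δ) (general single-qubit rotation up to phase),
RX/RY/RZ, CNOT, IsingXX(φ) = exp(−i φ/2 · X⊗X), and a two-branch
conditional U3 used for quantum pooling. Gates are applied by tensor
contraction on the wire axes; a dense Kronecker-product oracle exists
only in the test suite.

**Quantum pooling by deferred measurement.** Pooling "measures" a wire
and conditions a U3 on the outcome. Collapsing the state would make it
stochastic and non-differentiable, so the package applies the
block-diagonal controlled operation |0⟩⟨0|⊗U3(b₀) + |1⟩⟨1|⊗U3(b₁)
instead. By the deferred-measurement principle this is *exactly*
equivalent, for every later Z-expectation on other wires, to explicitly
collapsing into each outcome and probability-averaging; the equivalence
is asserted against an explicit collapse-and-average oracle at 1e-10.
Measured wires are never acted on after their pooling gate.

**Embeddings.** Angle embedding applies RY(xᵢ) per qubit to |0…0⟩ and
requires xᵢ ∈ [0, π] (half of the 2π period, so distinct inputs stay
distinguishable). Amplitude embedding L2-normalizes a real feature
vector into the first amplitudes and zero-pads at the tail (250 features
→ 8 qubits, 6 pads; 54 → 6 qubits, 10 pads). Tail placement keeps the
real features contiguous; an all-zero vector is rejected.

**Gradients.** Readout is the Pauli-Z expectation of designated wires.
Derivatives with respect to gate angles use reverse (adjoint) mode: the
observable vector is back-propagated through the inverse gates while the
state is un-computed, giving the full gradient in O(#gates) gate
applications independent of the parameter count. Each gate contributes
its analytic matrix derivative. The contract is oracle-based: gradients
match central finite differences (step 1e-4) to 1e-5 relative tolerance;
the differentiation *mechanism* is an implementation detail. For the
sliding-kernel layers the per-channel kernel circuits (4 qubits, 16×16)
are additionally compiled to explicit unitaries with per-parameter
derivative matrices, which turns the batched adjoint into a handful of
einsums; this fast path is algebraically identical to gate-by-gate
application and is tested against it.

## Architectures

**AEPQC** (amplitude-embedding PQC, 8 qubits, 112 trainable angles).
The pruned 25×10 window is flattened channel-major to 250 features and
amplitude-embedded. The circuit is: a U3 layer on all wires → IsingXX on
even pairs (0,1)…(6,7) → U3 layer → IsingXX on odd pairs with
wrap-around (1,2)…(7,0) → U3 layer → an IsingXX ring over all eight
neighbouring pairs → two-branch conditional-U3 pooling measuring wires
1, 3, 5, 7 onto 0, 2, 4, 6. Class scores are ⟨Z⟩ on wires 0 and 2 (the
two lowest-index surviving wires). *Design note:* the narrative
description of this architecture (three U3 layers, even+odd IsingXX
pairs, four pooled pairs) sums to 104 parameters, not the required 112;
the reference figure was not available, so the package completes the
layout with the pre-pooling entangling ring (8 parameters), which both
restores the printed count and makes the pooling measurements
informative about the rest of the register. The builder hard-fails if
the count is not exactly 112, so the layout is machine-checked.

**QCNN.** Per channel, a 4-qubit kernel slides over the 10 temporal
features with window 4 / stride 2, producing 2 outputs (⟨Z⟩ on wires 0
and 2) per position — length L → L−2 per layer, 10→8→6→4→2 over four
layers. Kernel weights are shared across positions (convolution
semantics) but separate per channel and per layer. Outputs in [−1, 1]
are mapped affinely to [0, π] (x ↦ (x+1)π/2) before re-embedding in the
next layer. Two kernels:

* **K1** (light, 8 parameters): RY + RZ per wire, circular CNOT
  entanglement, readout on wires 0 and 2.
* **K2** (39 parameters): U3 layer → IsingXX(0,1),(2,3) → U3 layer →
  IsingXX(1,2) → U3 on wires 1 and 3 → single-branch conditional-U3
  pooling 1→0 and 3→2 (identity on outcome |0⟩). Every wire carries
  exactly three U3-type gates (9 parameters per wire) plus the three
  entangling parameters.

The 27×2 channel outputs are fused by either the **c_head** — a 6-qubit
amplitude-embedding circuit (RY, RZ, RX per wire = 18 parameters, CNOT
ring, readout wires 0 and 1) — or a columnwise reduction: `avg`, `max`,
or `amax` (value of largest magnitude, sign preserved). Softmax is
applied only inside the loss; the scores themselves are Z-expectations.

**Initialization.** Uniform on [−π/10, π/10] per angle, drawn from a
seeded generator. Small angles keep the initial circuits near the
identity; the choice is a package convention (results are reported over
10 seeds precisely because initialization matters at these model sizes).

## Preprocessing

Trials (30 s at 10 Hz) are truncated to the half-open [3 s, 15 s)
post-stimulus window (0-based samples [30, 150)), where the hemodynamic
response is expected, and cut into 12 non-overlapping 10-sample windows
that inherit the trial label. Scaling is

    x_scaled = arctan((x − Q2) / (Q3 − Q1)),

with per-channel quartiles (linear "type 7" interpolation) pooled over
all training samples of the channel — channels have distinct optode
gains, while time points within a channel share a scale. The arctan
bounds heavy outliers inside (−π/2, π/2); adding a single |x| = 1e6
outlier to a 120-sample channel moves other scaled values by < 0.05. A
zero-IQR channel raises an error naming the channel. The shift x + π/2
maps into [0, π] for angle embedding (the unique pure shift). Scaler and
channel selection are fitted on the training fold only.

**Channel pruning (AEPQC).** Per channel, the score is the mean over the
10 within-window time points of |Pearson r| between the (scaled) feature
and the binary label across training windows; the two lowest-scoring
channels are dropped (ties: lower channel label first). Constant
features score 0. Channel labels are 1-based in all I/O and reports. On
the package's default synthetic world — where channels 22 and 24 carry
no class effect — pruning removes exactly those two, mirroring the
reported outcome on the real recordings.

## Protocol

* **Subject-independent (si):** leave-one-subject-out; with 14 subjects,
  1560 training and 120 validation windows per fold; learning rate 0.1.
* **Subject-dependent (sd):** per subject, first six recorded trials
  (3 fear / 3 non-fear → 72 windows) train, last four (48 windows)
  validate; learning rate 0.005. The recorded trial order must permit
  the 3/3 balance, otherwise the split is rejected.

Training is full-batch: one Adam step (β₁ = 0.9, β₂ = 0.999, ε = 1e-8)
per epoch on the whole training set, cross-entropy on softmaxed scores.
Early stopping fires after 5 epochs without a strictly lower validation
loss, gated on training accuracy having reached 75% at some epoch — the
gate prevents stopping on a by-chance-small validation loss before the
model has learned. A cap of 200 epochs guarantees termination if the
gate is never reached. Train metrics are recorded from the pre-update
forward pass (the one that produced the gradient), validation metrics
after the update; the reported accuracy is the one at the stopping
epoch, with the best-validation-loss epoch also logged. Every repetition
re-initializes weights from one of 10 seeds (0–9 by default); nothing
else is stochastic, so (seed, data, config) fully determines a run.

## Metrics

**Chance threshold.** With n validation windows, a model beats chance
when the lower bound of the 95% Wilson score interval of its accuracy
exceeds 0.5 (z = 1.959964; the printed thresholds are reproduced exactly
with this value and are insensitive to 1.96 at the grid precision). The
minimum such accuracy is found by a 0.01-percentage-point grid scan:
58.95% for n = 120, 64.15% for n = 48.

**Occlusion importance.** For a trained model and an input batch, each
channel is masked in turn and the importance of channel i is
mean |baseline − masked_i| over batch and score elements, normalized to
sum 1 across the analyzed channels (the 25 kept ones for AEPQC).
Masking zeroes the *post-arctan* values — zero is the channel's training
median there — which the QCNN's [0, π] shift carries to π/2 at the model
input (AEPQC, which embeds the arctan-scaled values directly, masks to
0). Masking the final shifted input to a literal 0 was evaluated and
rejected: 0 is an out-of-distribution extreme angle, and the resulting
attributions are near-uniform even for models that demonstrably use a
single channel. The "output" differenced is the pre-softmax score
vector; a softmax-probability variant is exposed as an option. A model
whose outputs never change yields uniform importances with a warning.

Confusion matrices are 2×2 counts normalized per true-class row.
Aggregate tables report per-subject mean and SD over seeds plus a Mean
row (mean of subject means, SD across subject means; population SD
throughout — the source convention is unstated).

## Synthetic data

The generator emulates the structure of the public VR height-fear
dataset the classifiers target: 14 subjects × 10 balanced trials × 27
channels × 30 s at 10 Hz, alternating fear/non-fear so the first six
trials are 3/3. Fear trials add `effect_amplitude × (1 + g_s) × HRF` to
the informative channels, with g_s ~ N(0, 0.2) a per-subject gain and
the HRF a peak-normalized double-gamma (peak 6 s, undershoot 16 s, ratio
1/6) delayed 3 s after stimulus onset — so the response sits inside the
3–15 s analysis window. All channels carry N(0, noise_sd²) white noise,
and 0.5% of samples are replaced by N(0, (100·noise_sd)²) spikes to
exercise the robust scaler. Defaults: noise_sd 1, effect_amplitude 3
(the effect/noise = 3 recovery regime), informative channels = all but
22 and 24 (giving channel pruning a known right answer).

What a green test does *not* establish: the generator has no Mayer
waves, systemic confounds, channel covariance or non-stationarity, so
synthetic accuracies say nothing about accuracy on real recordings — the
recovery tests only establish that the pipeline finds structure when it
is present (mean LOSO accuracy above the n = 120 chance threshold at
effect/noise = 3) and finds none when it is absent (accuracy within
[40%, 60%] at zero effect). The published cross-validation accuracies on
the real dataset require that dataset and are out of scope here; the
pipeline reads the same on-disk layout, so they can be attempted by
supplying the real recordings.

## Numerical choices and limitations

* Gate unitarity holds to 1e-12, engine-vs-oracle agreement to 1e-10,
  gradient-vs-finite-difference to 1e-5 relative (step 1e-4).
* Kernel outputs are clipped to [−1, 1] (guarding 1e-16 overshoots)
  before the inter-layer remap; model inputs are range-checked with a
  1e-9 tolerance.
* Fusion `max`/`amax` backward routes the gradient to the arg-max
  channel (a subgradient; ties resolve to the first index).
* The statevector engine is dense: fine through the 8-qubit AEPQC,
  not intended beyond ~12 qubits. No shot noise or device noise is
  modelled; expectations are exact, as in the study's simulator setup.
* Multi-class heads, mini-batching, learning-rate schedules and
  trainable embeddings are out of scope.
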