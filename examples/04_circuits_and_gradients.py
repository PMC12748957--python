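"""The statevector core: gates, embeddings, pooling and adjoint gradients.

Builds a Bell state from the supported gate set, shows deferred-
measurement pooling (a conditional U3 keeps the state pure while
reproducing collapse-and-average statistics), and differentiates a
circuit's Pauli-Z readout with respect to its gate angles.
"""

import numpy as np

from qfnirs import (
    Circuit,
    GateSpec,
    QuantumState,
    apply_gate,
    circuit_grad,
    expect_z,
    pool_conditional_u3,
)
from qfnirs.core import circuit_to_text, run_circuit

# Bell state: RY(pi/2) on qubit 0, then CNOT
bell = Circuit(2, (GateSpec("RY", (0,), (np.pi / 2,)), GateSpec("CNOT", (0, 1))),
               readout=(0, 1))
state = run_circuit(bell)
print("Bell amplitudes:", np.round(state.amplitudes.real, 4))
print(circuit_to_text(bell))

# quantum pooling: measure qubit 0, rotate qubit 1 by U3(pi,0,0) only on |1>
plus = apply_gate(QuantumState.zero(2), GateSpec("RY", (0,), (np.pi / 2,)))
pooled = pool_conditional_u3(plus, 0, 1, [0, 0, 0, np.pi, 0, 0])
print(f"<Z> on the pooled-into qubit: {expect_z(pooled, 1):+.4f} "
      "(= 0.5*(+1) + 0.5*(-1): the measured qubit is |0>/|1> with p=1/2)")

# adjoint gradient of <Z_0> for a small parameterized circuit
circ = Circuit(
    2,
    (
        GateSpec("U3", (0,), (0.4, -0.2, 0.7)),
        GateSpec("IsingXX", (0, 1), (0.9,)),
        GateSpec("RY", (1,), (1.1,)),
    ),
    readout=(0,),
)
vals, jac = circuit_grad(circ)
print(f"<Z0> = {vals[0]:+.6f}")
print("d<Z0>/d(angles) =", np.round(jac[0], 6))
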