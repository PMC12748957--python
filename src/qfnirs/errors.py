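"""Exception hierarchy used across the package.

Everything derives from :class:`QfnirsError` so callers can catch broadly;
the leaf classes mirror the distinct failure modes of the contracts
(shape vs. range vs. data-integrity vs. internal-consistency problems).
"""


class QfnirsError(Exception):
    """Base class for all package errors."""


class ContractError(QfnirsError, ValueError):
    """A precondition of an operation was violated (bad wires, counts, ...)."""


class UnsupportedGateError(ContractError):
    """Gate kind is not part of the supported gate set."""


class RangeError(ContractError):
    """A numeric input lies outside its required interval."""


class ShapeError(ContractError):
    """An array input has the wrong shape."""


class CapacityError(ContractError):
    """A vector does not fit into the requested number of qubits."""


class NormalizationError(ContractError):
    """A vector cannot be normalized (all-zero input)."""


class DataError(QfnirsError, ValueError):
    """A dataset violates the expected layout or labelling."""


class DegenerateDataError(DataError):
    """Data is degenerate for the requested operation (e.g. zero IQR)."""


class ConfigError(QfnirsError, ValueError):
    """Mutually inconsistent or invalid configuration."""


class TrainingError(QfnirsError, RuntimeError):
    """Training aborted (non-finite loss or similar)."""


class BuildVerificationError(ContractError):
    """A constructed architecture failed its structural self-check."""
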