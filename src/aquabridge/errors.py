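"""Exception hierarchy."""


class AquaBridgeError(Exception):
    """Base class for all package errors."""


class FormatError(AquaBridgeError, ValueError):
    """A structure file could not be parsed (message names the offending line)."""


class EmptyInputError(AquaBridgeError, ValueError):
    """An input that must be non-empty was empty (no atoms, no waters, ...)."""


class SelectionError(AquaBridgeError, KeyError):
    """A chain/residue/water selection referenced entities that do not exist."""


class GridError(AquaBridgeError, ValueError):
    """Lattice construction failed (bad dims, structure does not fit, ...)."""


class ConvergenceError(AquaBridgeError, RuntimeError):
    """Iterative solver did not reach tolerance; carries the residual history."""

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = list(residuals) if residuals is not None else []
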