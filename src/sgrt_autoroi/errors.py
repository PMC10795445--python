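"""Exception hierarchy shared by all modules.

CLI exit codes map onto these: invalid input/parameters -> 2,
degenerate geometry -> 3.
"""


class SgrtError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SgrtError, ValueError):
    """A configuration or shape parameter is outside its allowed range."""


class InvalidInputError(SgrtError, ValueError):
    """An input object violates a precondition (wrong size, empty, mismatched)."""


class DegenerateGeometryError(SgrtError, RuntimeError):
    """A geometric construction collapsed (empty row, inverted bounds, ...)."""


class TrainingDivergedError(SgrtError, RuntimeError):
    """The regression loss became non-finite during training."""
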