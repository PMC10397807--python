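"""Exception hierarchy for densfit."""


class DensfitError(Exception):
    """Base class for all densfit errors."""


class MapFormatError(DensfitError):
    """Raised when a density-map file cannot be parsed."""


class ModelFormatError(DensfitError):
    """Raised when an atomic-model file cannot be parsed or is empty."""


class DegenerateInputError(DensfitError):
    """Raised for inputs with no usable signal (e.g. a constant map)."""


class AlignmentError(DensfitError):
    """Raised when rigid-body alignment cannot find any model/map overlap."""


class MinimizationError(DensfitError):
    """Raised when energy minimization diverges."""


class OptionalDependencyError(DensfitError):
    """Raised when an optional external tool (e.g. a GOAP executable) is absent."""
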