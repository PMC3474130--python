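"""Exception hierarchy used across the package."""


class TdcsteerError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(TdcsteerError, ValueError):
    """A numeric argument is out of range or non-finite."""


class ConfigurationError(TdcsteerError, ValueError):
    """Inconsistent model configuration (missing labels, bad spec, ...)."""


class DimensionError(TdcsteerError, ValueError):
    """Mismatched array shapes or grids."""


class IllPosedProblemError(TdcsteerError, ValueError):
    """The discrete problem has no unique solution (e.g. no grounded plane)."""


class AssemblyError(TdcsteerError, RuntimeError):
    """The discrete operator failed a structural sanity check."""


class SolverError(TdcsteerError, RuntimeError):
    """The linear solver did not converge."""


class PlacementError(TdcsteerError, ValueError):
    """An electrode could not be placed on the head surface."""


class EmptyRegionError(TdcsteerError, ValueError):
    """A region of interest contains no voxels."""


class InfeasibleProblemError(TdcsteerError, RuntimeError):
    """No feasible electrode-current pattern was found."""

    def __init__(self, message, most_violated=None, violation=None):
        super().__init__(message)
        self.most_violated = most_violated
        self.violation = violation
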