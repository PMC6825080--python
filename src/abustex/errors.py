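"""Exception hierarchy shared across the package."""


class AbustexError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(AbustexError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateROIError(AbustexError, ValueError):
    """The masked region carries no usable grey-level variation."""


class EmptyMatrixError(AbustexError, ValueError):
    """A texture matrix could not be populated (no valid pairs/runs/zones)."""


class DegenerateVarianceError(AbustexError, ValueError):
    """A variance required by a statistical test is numerically zero."""
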