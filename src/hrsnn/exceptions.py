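"""Exception types shared across the package."""


class HRSNNError(Exception):
    """Base class for all package errors."""


class SpecificationError(HRSNNError, ValueError):
    """A parameter distribution or model specification is invalid."""


class ConfigurationError(HRSNNError, ValueError):
    """A structural configuration is infeasible (grid capacity, dt guard, ...)."""


class ShapeError(HRSNNError, ValueError):
    """Array shapes or source counts do not line up."""
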