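"""Exception hierarchy shared across the package."""


class ArmcycleError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ArmcycleError, ValueError):
    """A parameter or input violates a documented precondition."""


class GeometryError(ArmcycleError, ValueError):
    """Simulated linkage geometry is infeasible (e.g. unreachable crank)."""


class FormatError(ArmcycleError, ValueError):
    """A file does not conform to the documented on-disk format."""


class SchemaError(FormatError):
    """A required column or marker is missing from an input file."""
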