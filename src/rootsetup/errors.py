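"""Exception hierarchy shared across the package."""


class RootSetupError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(RootSetupError, ValueError):
    """Degenerate or invalid geometric input (collinear plane points,
    zero-length axes, undefined projection planes, ambiguous lingual
    direction, ...)."""


class MeshIntegrityError(RootSetupError, ValueError):
    """A mesh does not satisfy the requirements of the requested
    operation (not watertight, non-positive volume)."""


class InsufficientDataError(RootSetupError, ValueError):
    """Too few observations for the requested statistic."""


class UndefinedStatisticError(RootSetupError, ValueError):
    """The statistic is undefined for the given data (e.g. ICC with zero
    total variance)."""


class ParameterError(RootSetupError, ValueError):
    """Invalid configuration or template parameters."""


class LayoutError(RootSetupError, ValueError):
    """Generated arch geometry is self-colliding."""


class ParseError(RootSetupError, ValueError):
    """A data file does not match its schema."""


class ValidationError(RootSetupError, ValueError):
    """A data file parses but violates a semantic constraint
    (duplicate FDI ids, missing setups, ...)."""


class FormatError(RootSetupError, ValueError):
    """Unreadable or truncated mesh / data file."""
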