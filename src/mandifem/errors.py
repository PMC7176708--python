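"""Exception hierarchy used across the package."""


class MandifemError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(MandifemError, ValueError):
    """An argument violates a documented precondition."""


class GeometryError(MandifemError):
    """A geometric operation produced or received invalid geometry."""


class MappingError(MandifemError):
    """A landmark or attachment arc could not be mapped onto the mesh."""


class SolverError(MandifemError):
    """The linear system is singular or otherwise unsolvable."""


class FormatError(MandifemError, ValueError):
    """A data file does not follow the expected dialect."""


class DegenerateResultError(MandifemError):
    """A statistical operation returned a degenerate (rank-0) result."""
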