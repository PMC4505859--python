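"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`PipsitesError`, so callers can catch one type at pipeline level.
"""


class PipsitesError(Exception):
    """Base class for all package errors."""


class ValidationError(PipsitesError, ValueError):
    """Invalid argument or inconsistent system state."""


class ParseError(PipsitesError, ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        elif line is not None:
            loc += f" [line {line}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class SchemaError(PipsitesError, ValueError):
    """A tabular file or config violates the expected schema."""


class IntegrityError(PipsitesError, RuntimeError):
    """A packaged data file failed its checksum."""


class IntegrationError(PipsitesError, RuntimeError):
    """The integrator produced a non-finite force or coordinate."""


class DegenerateGeometryError(PipsitesError, ValueError):
    """A geometric operation received degenerate input (e.g. collinear beads)."""
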