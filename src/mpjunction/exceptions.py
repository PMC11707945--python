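"""Exception hierarchy shared across the package."""


class MPJunctionError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MPJunctionError):
    """Malformed or out-of-contract input (wrong units, non-finite values, ...)."""


class ConfigurationError(MPJunctionError):
    """Inconsistent or incomplete run configuration."""


class InsufficientDataError(MPJunctionError):
    """Too few observations or point pairs for the requested computation."""


class DegenerateConfigurationError(MPJunctionError):
    """Point configuration with no unique solution (collinear or coincident fiducials)."""


class InvalidGeometryError(MPJunctionError):
    """Self-intersecting, open, or zero-area polygon."""


class NoLesionError(MPJunctionError):
    """Distance query against a tracing with no retained lesion focus."""


class ParseError(MPJunctionError):
    """Unreadable or malformed input file; message names the offending row/feature."""
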