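"""Exception types shared across the package."""


class TendrilError(Exception):
    """Base class for all package errors."""


class DegenerateGeometryError(TendrilError):
    """Raised when a geometric primitive receives degenerate input
    (coincident points, collinear circle data, zero-length polylines)."""


class ValidationError(TendrilError):
    """Raised when a config, table or track violates its invariants."""


class NotConvergedError(TendrilError):
    """Raised when a result is requested from a fit that did not converge."""
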