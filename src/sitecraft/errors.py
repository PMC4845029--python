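"""Exception taxonomy shared across modules."""


class SitecraftError(Exception):
    """Base class for all package-specific errors."""


class UsageError(SitecraftError, ValueError):
    """The caller violated an operation's contract (bad arguments)."""


class FormatError(SitecraftError, ValueError):
    """A tabular or coordinate file does not conform to its dialect."""


class StructuralError(SitecraftError, ValueError):
    """Inconsistent molecular structure (atom mismatch across frames etc.)."""


class DegenerateGeometryError(SitecraftError, ValueError):
    """Geometry is degenerate (coincident/collinear points, zero vectors)."""
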