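"""Exception hierarchy for the vesselgame package."""


class VesselGameError(Exception):
    """Base class for all package errors."""


class InvalidLevelError(VesselGameError):
    """Level id outside the 1-7 range of the level table."""


class DegenerateGeometryError(VesselGameError):
    """Geometry input that cannot be stroked or measured (e.g. duplicate points)."""


class GenerationError(VesselGameError):
    """Scene generation exhausted its retry budget without meeting constraints."""


class ConfigError(VesselGameError):
    """Inconsistent run configuration (e.g. limited FOV with radius <= 0)."""


class ProtocolError(VesselGameError):
    """Malformed pointer-event stream (e.g. release without press)."""

    def __init__(self, message: str, index: int | None = None):
        super().__init__(message)
        self.index = index


class InsufficientDataError(VesselGameError):
    """Fewer observations than the statistic requires."""


class DegenerateComparisonError(VesselGameError):
    """Two-sample comparison where both variances are zero."""


class DataError(VesselGameError):
    """Trial data missing required levels or rows."""


class SchemaError(VesselGameError):
    """File does not match the documented schema."""
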