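"""Exception hierarchy for the transport engine and its physics modules."""


class CarbonMCError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(CarbonMCError):
    """Non-positive dimensions, disjoint grids, or other geometry defects."""


class ConfigurationError(CarbonMCError):
    """Missing or inconsistent configuration (materials, tables, parameters)."""


class InvalidEnergyError(CarbonMCError):
    """Kinetic energy outside the physical or tabulated domain."""


class InvalidAngleError(CarbonMCError):
    """Scattering angle outside its allowed interval."""


class ExtrapolationError(CarbonMCError):
    """Lookup outside a table grid where extrapolation is forbidden."""


class InvalidMaterialError(CarbonMCError):
    """Material with no usable interaction channel (all cross-sections zero)."""


class SamplingFailureError(CarbonMCError):
    """Rejection sampling exceeded its resample budget (corrupt tables)."""


class AmbiguousPeakError(CarbonMCError):
    """Profile has no well-defined interior maximum."""
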