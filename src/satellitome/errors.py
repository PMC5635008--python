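"""Exception types shared across the package."""


class SatellitomeError(Exception):
    """Base class for package errors."""


class InvalidParameterError(SatellitomeError, ValueError):
    """A parameter violates an operation's precondition."""


class InvalidAlphabetError(SatellitomeError, ValueError):
    """A sequence contains characters outside A/C/G/T."""


class CapacityError(SatellitomeError, ValueError):
    """Planted arrays do not fit into the background sequence."""


class SamplingError(SatellitomeError, ValueError):
    """A read sample was requested that exceeds the library."""


class UndefinedRatioError(SatellitomeError, ValueError):
    """log2 abundance ratio requested with a non-positive abundance."""


class DivergenceUndefinedError(SatellitomeError, ValueError):
    """Kimura distance is undefined (saturated substitution fractions)."""


class UndefinedCorrelationError(SatellitomeError, ValueError):
    """Rank correlation requested on constant input."""


class InfeasibleScanError(SatellitomeError, ValueError):
    """Multimer scan impossible: monomer multiple longer than any read."""
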