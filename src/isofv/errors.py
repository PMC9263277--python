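"""Exception hierarchy for the isofv pipeline."""


class IsofvError(Exception):
    """Base class for all isofv-specific errors."""


class InvalidParameterError(IsofvError, ValueError):
    """A parameter value is outside its admissible range (e.g. cutoff >= Nyquist)."""


class MalformedInputError(IsofvError, ValueError):
    """Input data violates a structural contract (e.g. non-uniform time grid)."""


class NoPlateauError(IsofvError, RuntimeError):
    """No sample run satisfies the isokinetic velocity tolerance."""


class InsufficientRepetitionsError(IsofvError, ValueError):
    """Fewer repetition peaks than the number required for best-peak selection."""


class InvalidMeasurementError(IsofvError, ValueError):
    """A measured quantity is non-physical (e.g. non-positive peak torque)."""


class NonPhysicalProfileError(IsofvError, ValueError):
    """A fitted force-velocity profile has a non-negative slope; v0 is undefined."""


class DegeneratePairError(IsofvError, ValueError):
    """The two points of a 2-point profile share the same velocity."""


class RankDeficiencyError(IsofvError, ValueError):
    """Too few distinct velocities for the requested regression."""


class UndefinedICCError(IsofvError, ValueError):
    """Intraclass correlation is undefined (zero between-subject variance)."""


class UndefinedCVError(IsofvError, ValueError):
    """Coefficient of variation is undefined (near-zero grand mean)."""


class InsufficientSampleError(IsofvError, ValueError):
    """Sample too small for the requested statistic."""


class InsufficientVariationError(IsofvError, ValueError):
    """Sample has no variation; the statistic is undefined."""


class ConfigError(IsofvError, ValueError):
    """Configuration is invalid; the message lists the offending fields."""
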