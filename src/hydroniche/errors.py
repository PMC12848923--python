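"""Exception hierarchy.

Everything derives from :class:`HydronicheError` so callers can catch the
package's failures with one clause; most also derive from ``ValueError``
because they signal bad inputs rather than internal faults.
"""


class HydronicheError(Exception):
    """Base class for all hydroniche errors."""


class InvalidSettingsError(HydronicheError, ValueError):
    """Generator or model settings violate their invariants."""


class DegenerateInputError(HydronicheError, ValueError):
    """Input is structurally valid but statistically degenerate
    (too few points, zero variance, fewer than two sources...)."""


class MissingSourceError(HydronicheError, ValueError):
    """A soil layer required as a mixing source has no samples."""


class UnknownGroupError(HydronicheError, KeyError):
    """A plant functional group has no configured uptake target."""


class MissingGroupError(HydronicheError, ValueError):
    """A site lacks the functional group needed for a statistic."""


class UndefinedRatioError(HydronicheError, ZeroDivisionError):
    """Herb-to-shrub ratio requested with non-positive denominator."""


class InsufficientDataError(HydronicheError, ValueError):
    """Not enough observations/draws for the requested statistic."""


class MappingError(HydronicheError, KeyError):
    """A label cannot be mapped (layer -> depth group, etc.)."""


class UnsupportedConfigurationError(HydronicheError, ValueError):
    """A computation was requested in a mode its assumptions exclude."""


class IntegrationError(HydronicheError, RuntimeError):
    """Trajectory integration produced non-finite values."""

    def __init__(self, message: str, t: float | None = None):
        super().__init__(message)
        self.t = t


class PipelineError(HydronicheError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
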