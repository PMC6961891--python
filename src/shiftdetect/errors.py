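"""Exception types shared across the toolkit."""


class ShiftDetectError(Exception):
    """Base class for all shiftdetect errors."""


class SeriesError(ShiftDetectError, ValueError):
    """Invalid population time series (gaps, duplicates, non-positive values)."""


class ConfigurationError(ShiftDetectError, ValueError):
    """Inconsistent analysis configuration (e.g. AICc with too small a segment)."""


class FitError(ShiftDetectError, RuntimeError):
    """A segment fit could not be attempted at all (too few transition pairs)."""


class InfeasibleScenarioError(ShiftDetectError, ValueError):
    """No admissible break placement exists for the requested scenario."""
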