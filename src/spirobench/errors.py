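"""Exception hierarchy.

Every error the package raises deliberately derives from :class:`SpirobenchError`
so callers (and the CLI) can distinguish domain errors from genuine bugs.
"""


class SpirobenchError(Exception):
    """Base class for all spirobench domain errors."""


class ParameterInfeasibleError(SpirobenchError, ValueError):
    """A requested (FEV1, FVC, PEF, FET) combination cannot be realised by a
    smooth expiratory flow profile; the message names the violated constraint."""


class CalibrationError(SpirobenchError, ValueError):
    """Sensor calibration data are insufficient or inconsistent (e.g. fewer than
    two distinct concentrations, or a fit too nonlinear to trust)."""


class TraceFormatError(SpirobenchError, ValueError):
    """A trace file violates the CSV dialect (missing column, nonuniform
    timestamps, long NaN runs); carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class MetricError(SpirobenchError, ValueError):
    """A maneuver segment is unusable for metric computation (too short, no
    detectable rise, ...)."""


class GradingUnavailableError(SpirobenchError, ValueError):
    """Session grading requested with fewer than two maneuvers."""


class UndefinedCorrelationError(SpirobenchError, ValueError):
    """Pearson correlation undefined (zero variance or too few pairs)."""


class UnbalancedDesignError(SpirobenchError, ValueError):
    """Two-factor ANOVA design has an empty cell; the message names it."""


class UnsupportedDemographicsError(SpirobenchError, KeyError):
    """No reference equation registered for the requested demographic stratum."""


class GasQuantificationError(SpirobenchError, ValueError):
    """Gas summary window too short or otherwise unusable."""
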