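"""Exception types shared across the pipeline stages."""


class OryxhrError(Exception):
    """Base class for all package errors."""


class ParameterError(OryxhrError, ValueError):
    """A simulation or analysis parameter violates its constraints.

    The message names the offending field.
    """


class InputError(OryxhrError, ValueError):
    """An input object (strip, record set) is empty or malformed."""


class UndefinedRateError(OryxhrError, ValueError):
    """A heart rate was requested from fewer than two beats/senses."""


class FittingError(OryxhrError, ValueError):
    """A regression could not be fitted (too few points, zero variance)."""


class SingularDesignError(OryxhrError, ValueError):
    """The model design matrix is rank deficient after constraints."""


class SchemaError(OryxhrError, ValueError):
    """A CSV file does not match the expected schema; names the column."""


class UnsupportedLatitudeError(OryxhrError, ValueError):
    """Photoperiod requested for a polar latitude (|lat| > 66.5)."""


class SeasonRangeError(OryxhrError, ValueError):
    """A date falls outside the built-in solstice/equinox table."""


class PipelineError(OryxhrError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
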