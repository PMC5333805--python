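"""Exception hierarchy shared across the pipeline.

Every stage raises subclasses of :class:`TwitchVAError` so callers can
distinguish bad inputs from bugs; :class:`PipelineError` wraps a stage
failure with the stage's identity for end-to-end runs.
"""


class TwitchVAError(Exception):
    """Base class for all package errors."""


class ParameterError(TwitchVAError, ValueError):
    """A scalar parameter is outside its admissible range."""


class UnitsError(TwitchVAError):
    """Operation applied to a trace in the wrong units."""


class ConfigurationError(TwitchVAError):
    """Protocol or filter configuration is internally inconsistent."""


class BoundsError(TwitchVAError):
    """A requested analysis window falls outside the trace extent."""


class MissingDataError(TwitchVAError):
    """Required trials or measurements are absent."""


class ValidationError(TwitchVAError):
    """Structural validation of a dataset, manifest or design failed."""


class QCWarning(UserWarning):
    """Non-fatal quality-control flag (e.g. non-zero resting baseline)."""


class PipelineError(TwitchVAError):
    """Failure inside a multi-stage run, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
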