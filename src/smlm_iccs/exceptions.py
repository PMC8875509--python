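"""Exception hierarchy for the SMLM-ICCS pipeline.

Errors are split into configuration problems (bad parameters or file
dialects), input problems (empty or degenerate data), and numerical
problems (insufficient region of interest, ill-conditioned geometry).
"""


class SMLMICCSError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SMLMICCSError):
    """A parameter, dialect or config file is invalid."""


class EmptyInputError(SMLMICCSError):
    """An input file or table contains no usable records."""


class EmptyChannelError(SMLMICCSError):
    """A requested channel holds zero localizations."""


class DegenerateInputError(SMLMICCSError):
    """An image is constant (zero variance) or otherwise uninformative."""


class InsufficientROIError(SMLMICCSError):
    """The region of interest is too small for the requested lag window."""


class DriftEstimationError(SMLMICCSError):
    """Drift cannot be estimated (e.g., no fiducial tracks available)."""


class ConditioningError(SMLMICCSError):
    """Landmark geometry is degenerate for the requested transform model."""


class PipelineError(SMLMICCSError):
    """A pipeline stage failed; carries the stage name and a hint."""

    def __init__(self, stage: str, message: str, hint: str = ""):
        self.stage = stage
        self.hint = hint
        text = f"stage '{stage}' failed: {message}"
        if hint:
            text += f" (hint: {hint})"
        super().__init__(text)
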