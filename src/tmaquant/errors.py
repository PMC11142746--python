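"""Exception types raised by the pipeline stages.

Each stage raises a specific subclass so the orchestrator can report which
stage failed and on which input.
"""


class TmaQuantError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TmaQuantError):
    """A parameter block or rule references something that does not exist."""


class GenerationError(TmaQuantError):
    """The synthetic generator could not realize the requested configuration."""


class DegenerateInputError(TmaQuantError):
    """The input carries no usable signal (e.g. constant image, one-class outcome)."""


class RegistrationConfidenceError(TmaQuantError):
    """Registration produced no trustworthy transform; carries the best score."""

    def __init__(self, message: str, score: float):
        super().__init__(f"{message} (best similarity score {score:.4f})")
        self.score = score


class InputDataError(TmaQuantError):
    """A required input file/table is missing or inconsistent."""


class FitConvergenceError(TmaQuantError):
    """A model fit failed (non-convergence, perfect/monotone separation)."""


class AnalysisError(TmaQuantError):
    """A statistical test cannot be run on the given strata (e.g. one stratum)."""
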