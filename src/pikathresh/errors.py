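"""Exception hierarchy shared across the pipeline stages."""


class PikathreshError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PikathreshError, ValueError):
    """A configuration or operation parameter violates its contract."""


class EmptyCommunityError(PikathreshError, ValueError):
    """A community metric was requested for an all-zero abundance vector."""


class CapacityError(PikathreshError, RuntimeError):
    """Rejection sampling could not place points at the requested spacing."""


class NearSingularityError(PikathreshError, ValueError):
    """A correlation matrix is too close to singular for the requested statistic."""


class StageError(PikathreshError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
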