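"""Error types shared across the package."""


class DegenerateDataError(ValueError):
    """Raised when a response matrix cannot support the requested analysis,
    e.g. an item column is constant after removing extreme-score persons."""


class DegenerateSplitError(DegenerateDataError):
    """Raised when a score split leaves one group empty."""


class NonConvergenceError(RuntimeError):
    """Raised when an iterative fit fails to converge within its cap.

    Carries the last iterate in ``last_params``.
    """

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params
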