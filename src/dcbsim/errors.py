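"""Exception hierarchy for dcbsim.

All validation-type failures derive from ``ValueError`` so that callers who
do not care about the fine distinction can catch a single base class;
runtime numerical failures derive from ``RuntimeError``.
"""


class ValidationError(ValueError):
    """Structurally invalid input (wrong shape, unknown label, bad config)."""


class DomainError(ValueError):
    """Value outside its mathematically admissible domain."""


class ResolutionError(ValueError):
    """Mesh spacing too coarse to resolve a geometric region."""


class ConfigurationError(ValueError):
    """A run was requested on inputs missing a required ingredient."""


class ConvergenceError(RuntimeError):
    """An iterative search could not reach its goal within its bounds."""


class NumericalError(RuntimeError):
    """A linear solve or time-step controller failed irrecoverably."""
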