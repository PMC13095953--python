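"""Exception hierarchy.

``ValidationError`` covers malformed inputs and parameters; ``InvalidRunError``
marks an assay run whose on-chip positive reference failed, which the
self-validation contract treats as a void result rather than a number.
"""


class BeadQuantError(Exception):
    """Base class for all package errors."""

    #: short machine-readable class used in CLI exit reporting
    error_class = "error"


class ValidationError(BeadQuantError, ValueError):
    """A parameter or input violates a documented precondition."""

    error_class = "validation"


class InvalidRunError(BeadQuantError, RuntimeError):
    """The positive-reference zone failed; the run is void, not quantifiable."""

    error_class = "invalid-run"


class EmptyZoneError(InvalidRunError):
    """A zone summary was requested for a zone containing no beads."""

    error_class = "empty-zone"
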