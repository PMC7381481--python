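"""Exception hierarchy for imrangio.

Every error raised by the library derives from :class:`ImrAngioError`, so
callers (and the CLI) can distinguish domain errors from programming bugs.
"""


class ImrAngioError(Exception):
    """Base class for all imrangio errors."""


class InvalidInputError(ImrAngioError, ValueError):
    """A numeric input violates its physiologic domain (names the field)."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class MissingFieldError(ImrAngioError, ValueError):
    """A required optional field is absent for the requested computation."""

    def __init__(self, field: str, message: str = "required field is missing"):
        self.field = field
        super().__init__(f"{field}: {message}")


class DegenerateHaemodynamicsError(ImrAngioError, ValueError):
    """Pressures are physiologically inconsistent (e.g. wedge >= distal)."""


class JoinError(ImrAngioError, ValueError):
    """Per-lesion records could not be joined (id / timepoint mismatch)."""


class PairingError(ImrAngioError, ValueError):
    """Pre/post lesion panels could not be paired per patient."""


class DegenerateLabelsError(ImrAngioError, ValueError):
    """A binary reference contains a single class; ROC is undefined."""


class UndefinedCorrelationError(ImrAngioError, ValueError):
    """A correlation is undefined because one input has zero variance."""


class IncompleteDesignError(ImrAngioError, ValueError):
    """A rating table has missing cells; the two-way ICC needs a full design."""


class InvalidSpecError(ImrAngioError, ValueError):
    """A quantile or cohort specification violates its invariants."""
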