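"""Exception types shared across the package."""


class PpideconError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(PpideconError, ValueError):
    """An argument violates an operation's preconditions."""


class SizeLimitError(PpideconError):
    """An exact computation was refused because the instance is too large."""


class DataError(PpideconError):
    """Input data is malformed or incomplete (e.g. a missing protein length)."""


class IntegrityError(PpideconError):
    """Derived artifacts are mutually inconsistent."""


class DegenerateCutError(PpideconError):
    """No balanced block partition of the core exists."""


class InfeasibleInstanceError(PpideconError):
    """The reduced instance admits no connected completion."""


class FitError(PpideconError):
    """A parameter fit could not be performed on the given reference."""
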