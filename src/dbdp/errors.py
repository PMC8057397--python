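"""Exception hierarchy shared by every pipeline stage.

Anticipated failure modes get their own class so callers (and the CLI's
exit-code mapping) can distinguish contract violations from bad inputs.
"""


class DbdpError(Exception):
    """Base class for all anticipated pipeline errors."""


class ContractError(DbdpError, ValueError):
    """A caller violated an operation's precondition (bad argument)."""


class EmptyInputError(DbdpError):
    """An operation received a series/file with no usable samples."""


class InsufficientDataError(DbdpError):
    """Input is valid but too short for the requested analysis."""


class UntrainableLabelsError(DbdpError):
    """Heuristic labeling produced no usable sleep or wake seed class."""


class NoRestingDataError(DbdpError):
    """Every (n, m) candidate in the resting-heart-rate search was disqualified."""


class NoFeaturesError(DbdpError):
    """Every epoch was excluded during feature extraction."""


class DegenerateSmoothingError(DbdpError):
    """Too few samples to fit a LOWESS trend."""
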