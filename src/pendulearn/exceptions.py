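"""Exception hierarchy for pendulearn.

All package-specific failures derive from :class:`PendulearnError` so callers
can catch a single base class.  Input-contract violations additionally derive
from :class:`ValueError` to stay idiomatic for library users.
"""


class PendulearnError(Exception):
    """Base class for all pendulearn errors."""


class InvalidStateError(PendulearnError, ValueError):
    """A dynamical state or signal contains non-finite values."""


class DegenerateSignalError(PendulearnError, ValueError):
    """A signal is constant (zero variance) where variation is required."""


class InsufficientDataError(PendulearnError, ValueError):
    """Not enough samples / participants for the requested computation."""


class DataCompletenessError(PendulearnError, ValueError):
    """A participant/block table is missing required entries."""


class EstimationError(PendulearnError, ValueError):
    """A parameter-estimation problem is ill-posed (e.g. rank deficient)."""


class DesignError(PendulearnError, ValueError):
    """A factorial design is unusable (empty cells, too few subjects)."""


class FormatError(PendulearnError, ValueError):
    """A data file does not conform to the expected layout."""
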