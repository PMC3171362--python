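"""Exception hierarchy for cpcm.

All user-facing errors derive from :class:`CpcmError` so callers can catch
one base class; each subclass maps to a distinct failure mode of the
pipeline (input parsing, binning constraints, degenerate posteriors).
"""


class CpcmError(Exception):
    """Base class for all cpcm errors."""


class EmptyInputError(CpcmError):
    """No usable probe rows remain after filtering."""


class DuplicatePositionError(CpcmError):
    """Two probes share a genomic position; the model needs strictly increasing coordinates."""


class InsufficientDataError(CpcmError):
    """Too few probes/gaps for the requested operation."""


class InvalidInputError(CpcmError):
    """Input values violate a precondition (e.g. non-positive gaps)."""


class ConstraintViolationError(CpcmError):
    """A partition violates the 1..300 observations-per-subinterval rule or has an empty bin."""


class DegeneratePartitionError(CpcmError):
    """A candidate split leaves zero genomic length on one side."""


class NoValidCandidateError(CpcmError):
    """Every candidate change subinterval was excluded from the posterior."""
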