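"""Exception hierarchy shared across tapdose modules."""


class TapdoseError(Exception):
    """Base class for all tapdose errors."""


class InvalidParameterError(TapdoseError, ValueError):
    """A scalar parameter is outside its physical domain."""


class InvalidChainError(TapdoseError, ValueError):
    """A decay chain is malformed (duplicates, cycles, degenerate rates)."""


class IncompleteDataError(TapdoseError, ValueError):
    """Required nuclear-data records are missing."""


class InvalidOrderError(TapdoseError, ValueError):
    """Timestamps supplied in a physically impossible order."""


class InvalidSampleError(TapdoseError, ValueError):
    """A biodistribution sample violates its invariants."""


class IncompleteTableError(TapdoseError, ValueError):
    """A biodistribution table lacks a usable standard."""


class MissingCellError(TapdoseError, KeyError):
    """Requested organ/timepoint cell absent from a group."""


class DegenerateInputError(TapdoseError, ValueError):
    """Zero-variance or otherwise degenerate statistical input."""


class EmptyChromatogramError(TapdoseError, ValueError):
    """A chromatogram contains no counts."""


class InvalidFormulaError(TapdoseError, ValueError):
    """A molecular formula contains an unknown element symbol."""


class AlignmentError(TapdoseError, ValueError):
    """Plate total and nonspecific wells use different concentration grids."""


class FitFailureError(TapdoseError, RuntimeError):
    """Nonlinear fit failed to converge after bounded restarts."""


class InsufficientDataError(TapdoseError, ValueError):
    """Too few data points for the requested computation."""


class MappingError(TapdoseError, KeyError):
    """Organ keys cannot be mapped between phantoms or tables."""


class ScenarioError(TapdoseError, ValueError):
    """A synthetic-data scenario is infeasible."""


class OrderingError(TapdoseError, ValueError):
    """A measurement history is not chronologically ordered."""
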