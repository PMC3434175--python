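"""Exception hierarchy for the cuefidelity package.

All package-specific failures derive from :class:`CueFidelityError` so callers
can catch the whole family; domain/argument violations additionally derive
from :class:`ValueError`.
"""

from __future__ import annotations


class CueFidelityError(Exception):
    """Base class for all cuefidelity errors."""


class DomainError(CueFidelityError, ValueError):
    """A parameter or input is outside its mathematical domain."""


class InsufficientDataError(CueFidelityError):
    """Too few trials or levels to attempt a fit."""


class DegenerateFitError(CueFidelityError):
    """The likelihood is flat or unbounded (e.g. chance-only or all-correct data).

    Carries a ``summary`` attribute describing the offending data.
    """

    def __init__(self, message: str, summary=None):
        super().__init__(message)
        self.summary = summary


class NoFacilitationError(CueFidelityError):
    """Bimodal threshold not below both unimodal thresholds; pooling k undefined."""


class SpecMismatchError(CueFidelityError):
    """An observer was asked to run a condition its mechanism cannot produce."""


class IncompleteDesignError(CueFidelityError):
    """A factorial analysis received a design with missing cells.

    Carries a ``missing`` attribute listing absent (subject, cell) combinations.
    """

    def __init__(self, message: str, missing=None):
        super().__init__(message)
        self.missing = missing or []


class SeriesAlignmentError(CueFidelityError):
    """Two time series that must be aligned have incompatible shapes or grids."""


class DivergenceError(CueFidelityError):
    """A closed-loop tracking simulation diverged (unstable controller gains)."""


class TableFormatError(CueFidelityError):
    """A delimited input table is malformed; message includes the line number."""
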