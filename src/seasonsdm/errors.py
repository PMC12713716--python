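"""Exception types shared across the package."""


class SeasonSDMError(Exception):
    """Base class for all package errors."""


class MissingLayerError(SeasonSDMError, KeyError):
    """A (variable, year, month) layer was requested but is not in the stack."""

    def __init__(self, variable: str, year: int, month: int):
        super().__init__(f"no layer for variable={variable!r} year={year} month={month}")
        self.variable = variable
        self.year = year
        self.month = month


class OutsideExtentError(SeasonSDMError, ValueError):
    """A point falls outside the grid extent."""


class InsufficientCandidatesError(SeasonSDMError, RuntimeError):
    """Not enough eligible cells to draw the requested pseudo-absences."""


class NoDissimilarCandidateError(SeasonSDMError, RuntimeError):
    """RSEP found no environmentally dissimilar candidate for a presence point."""


class DegenerateGeometryError(SeasonSDMError, ValueError):
    """Fewer than three non-collinear points; no convex hull exists."""


class DegenerateDensityError(SeasonSDMError, ValueError):
    """Constant values admit no kernel density estimate."""


class SingleClassError(SeasonSDMError, ValueError):
    """Scores/labels contain only one class; AUC and thresholds are undefined."""
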