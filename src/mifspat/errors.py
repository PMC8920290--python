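"""Exception types shared across the package."""


class MifspatError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MifspatError):
    """An input table is missing a required column or carries invalid values."""


class RowParseError(MifspatError):
    """A specific row of an input table could not be parsed."""


class UnknownMarkerError(MifspatError):
    """A phenotype refers to a marker column that does not exist."""


class DegenerateWindowError(MifspatError):
    """Fewer than three non-collinear points: no convex-hull window exists."""


class PointOutsideWindowError(MifspatError):
    """An edge-correction weight was requested for a point outside the window."""


class NotEstimableError(MifspatError):
    """Ripley's K (or its permutation null) is undefined for this input.

    Distinct from an estimate of zero: raised when there are too few
    positive cells (univariate n < 2, bivariate n1 or n2 = 0).
    """


class InfeasibleCutpointError(MifspatError):
    """No candidate cut-point pair satisfies the minimum-group-size constraint."""


class NonNestedGroupingError(MifspatError):
    """The abundance-only grouping is not a coarsening of the full grouping."""
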