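"""Exception hierarchy for the gmqn package."""


class GmqnError(Exception):
    """Base class for all gmqn errors."""


class FormatError(GmqnError):
    """A file could not be parsed in the expected delimited-text layout."""


class SchemaError(GmqnError):
    """A parsed file is missing required columns/fields or has a version mismatch."""


class ValidationError(GmqnError):
    """Input data violates a documented invariant (negative intensity, bad channel, ...)."""


class ParameterError(GmqnError):
    """A function argument is outside its valid domain."""


class DegenerateDataError(GmqnError):
    """Data cannot support the requested fit (constant input, too few values)."""


class ComponentCollapseError(GmqnError):
    """A mixture component's standard deviation collapsed below the floor."""

    def __init__(self, state: int, sd: float, floor: float):
        self.state = state
        super().__init__(
            f"mixture component (state {state}) collapsed: sd={sd:.3g} < floor={floor:.3g}"
        )


class ReferenceBuildError(GmqnError):
    """The reference distribution could not be built from the provided samples."""


class FitError(GmqnError):
    """A per-sample model fit failed."""
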