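"""Exception hierarchy for the foodshed package."""


class FoodshedError(Exception):
    """Base class for all package errors."""


class InvalidEntryError(FoodshedError):
    """A conversion-table entry violates its invariants (e.g. missing phi)."""


class LookupError_(FoodshedError):
    """A food id or geo-unit id could not be resolved."""


class ValidationError(FoodshedError):
    """An input value is out of its declared range."""


class UndefinedRatioError(FoodshedError):
    """A ratio (share, self-sufficiency) is requested with a zero denominator."""


class DelineationError(FoodshedError):
    """Foodshed delineation cannot proceed (e.g. centroid outside the grid)."""


class PipelineError(FoodshedError):
    """A pipeline stage failed; the message carries the stage name."""
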