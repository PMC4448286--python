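"""Exception hierarchy shared across the pipeline stages."""


class RipenetError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(RipenetError, ValueError):
    """A simulation spec violates its invariants."""


class InvalidInputError(RipenetError, ValueError):
    """Numerically invalid input (non-positive lengths, bad thresholds...)."""


class AlignmentError(RipenetError, ValueError):
    """Sample / line identifiers of two inputs do not agree."""


class EmptyInputError(RipenetError, ValueError):
    """An operation received an all-missing or empty vector/table."""


class CannotEstimateError(RipenetError, ValueError):
    """Variance components cannot be estimated from the given design."""


class UnknownTraitError(RipenetError, KeyError):
    """A trait id is absent from the trait matrix."""


class ShapeError(RipenetError, ValueError):
    """Matrix input has the wrong shape (e.g. non-square correlation)."""


class MissingLabelError(RipenetError, KeyError):
    """A network node lacks a required cluster label."""


class InvalidKError(RipenetError, ValueError):
    """Requested number of clusters is out of range."""


class IsolatedItemError(RipenetError, ValueError):
    """An item has undefined distance to every other item."""


class EmptyResultError(RipenetError, ValueError):
    """A filtering step removed every candidate item."""


class MalformedHierarchyError(RipenetError, ValueError):
    """An annotation file references a bincode whose parent is missing."""
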