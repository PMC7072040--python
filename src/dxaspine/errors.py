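"""Exception hierarchy for the dxaspine pipeline.

Every stage raises a subclass of :class:`DxaSpineError` so batch drivers can
catch pipeline failures without masking programming errors.
"""


class DxaSpineError(Exception):
    """Base class for all dxaspine errors."""


class InvalidInputError(DxaSpineError, ValueError):
    """An argument violates a documented precondition."""


class SizingError(InvalidInputError):
    """Requested phantom canvas is too small to hold all body structures."""


class AnatomyViolationError(DxaSpineError):
    """Segmentation could not satisfy the expected body layout.

    Carries the name of the anatomical expectation that failed
    (``"head"``, ``"legs"``, ``"pelvis"``, ``"spine"``).
    """

    def __init__(self, expectation: str, message: str | None = None):
        self.expectation = expectation
        super().__init__(message or f"anatomical expectation not met: {expectation}")


class InsufficientSpineError(DxaSpineError):
    """Too few usable spine rows to measure curvature."""


class UndefinedMarginError(InvalidInputError):
    """A confusion-table margin needed for a rate is empty."""


class DegenerateInputError(InvalidInputError):
    """Statistical input is degenerate (single class, zero variance, ...)."""
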