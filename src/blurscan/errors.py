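"""Exception hierarchy used across the package."""


class BlurscanError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(BlurscanError, ValueError):
    """A scan/classifier configuration violates its invariants."""


class InvalidScoreError(BlurscanError, ValueError):
    """A HER2 score outside {0, 1, 2, 3} (or {0, 1} for the binary task)."""


class SizeError(BlurscanError, ValueError):
    """A requested raster/mosaic exceeds the configured maximum size."""


class InvalidKernelError(BlurscanError, ValueError):
    """Blur kernel incompatible with the image it is applied to."""


class CoverageGapError(BlurscanError, ValueError):
    """Row step larger than the frame height would leave unscanned gaps."""


class OutOfBoundsError(BlurscanError, ValueError):
    """A motion trace leaves the (padded) slide area."""


class InsufficientInputError(BlurscanError, ValueError):
    """Too few frames to compute pairwise statistics."""


class NoScanLinesError(BlurscanError, ValueError):
    """Motion classification found no moving/static alternation."""


class NoBackgroundError(BlurscanError, ValueError):
    """No tissue-free background block available for white balancing."""


class EmptyTissueError(BlurscanError, ValueError):
    """No foreground tissue left after thresholding/filtering."""


class CellTooSmallError(BlurscanError, ValueError):
    """A grid cell fell below the minimum usable size."""


class LabelMismatchError(BlurscanError, ValueError):
    """Manifest grid shape does not match the segmented grid."""


class DegenerateDataError(BlurscanError, ValueError):
    """Training data contains fewer than two classes."""


class ShapeError(BlurscanError, ValueError):
    """Array shapes inconsistent with the model or metric contract."""


class EmptyInputError(BlurscanError, ValueError):
    """An aggregation operation received an empty repeat set."""


class UndefinedAggregateError(BlurscanError, ValueError):
    """All confidence values are zero; the weighted score is undefined."""


class UnreachableTargetError(BlurscanError, ValueError):
    """Requested indeterminate fraction cannot be reached on this curve."""


class UndefinedAUCError(BlurscanError, ValueError):
    """ROC/AUC undefined because only one class is present."""
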