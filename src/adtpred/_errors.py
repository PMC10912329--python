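"""Exception hierarchy shared across the package."""


class AdtpredError(Exception):
    """Base class for all package-specific errors."""


class MatrixFormatError(AdtpredError):
    """An on-disk matrix/features/barcodes triplet is malformed or inconsistent."""


class MatrixValidationError(AdtpredError):
    """A count matrix violates its invariants (negative or non-integer entries, ...)."""


class ModelFormatError(AdtpredError):
    """A serialized model file is truncated or missing a required section."""


class ModelVersionError(AdtpredError):
    """A serialized model declares a format version this package cannot read."""


class QCError(AdtpredError):
    """Quality-control filtering failed (e.g. every cell removed)."""


class NormalizationError(AdtpredError):
    """Normalization preconditions violated (zero-count cells, bad size factors)."""


class AlignmentError(AdtpredError):
    """Gene/protein/barcode name alignment between two objects failed."""


class FitError(AdtpredError):
    """Model fitting preconditions violated (too few cells, k too large, ...)."""
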