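"""Exception and warning types shared across the package."""


class AmbiquantError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(AmbiquantError, ValueError):
    """A user-supplied parameter is outside its valid range."""


class FormatError(AmbiquantError, ValueError):
    """An input file violates the expected on-disk layout or content rules."""


class NoCountsError(AmbiquantError, ValueError):
    """The count matrix contains no counts at all."""


class DegenerateSweepError(AmbiquantError, ValueError):
    """A calibration sweep is too degenerate to derive score weights from."""


class LowConfidenceKneeWarning(UserWarning):
    """The barcode-rank curve has no distinct knee; a fallback estimate was used."""


class QCWarning(UserWarning):
    """A QC quantity was computed under a degenerate condition (e.g. no counts)."""
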