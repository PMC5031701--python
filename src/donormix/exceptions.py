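"""Exception hierarchy for donormix.

All package errors derive from :class:`DonorMixError` so callers (and the
CLI) can distinguish pipeline-stage failures from programming errors.
"""


class DonorMixError(Exception):
    """Base class for all donormix errors."""


class PanelFormatError(DonorMixError):
    """A panel file (BED/VCF) is unreadable or violates the dialect."""


class EmptyPanelError(PanelFormatError):
    """A panel file contained no usable biallelic SNP records."""


class PileupFormatError(DonorMixError):
    """A pileup line is malformed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"pileup line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class CountsValidationError(DonorMixError):
    """A counts table fails validation against the panel."""


class SelectionError(DonorMixError):
    """Locus selection produced an unusable (empty) result."""


class InsufficientDataError(DonorMixError):
    """Too few informative loci to fit the mixture model."""


class EstimationError(DonorMixError):
    """The donor-fraction estimation failed (e.g. no replicate converged)."""


class UndefinedResultError(DonorMixError):
    """A requested statistic is undefined for the given input."""


class ConfigError(DonorMixError):
    """A run or simulation configuration is invalid."""
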