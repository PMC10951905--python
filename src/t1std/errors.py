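"""Exception hierarchy used across the package."""


class T1StdError(Exception):
    """Base class for all package-specific errors."""


class InputError(T1StdError):
    """A file or record violates an input precondition (unreadable DICOM,
    shape mismatch, empty mask, ...)."""


class ExtractionError(T1StdError):
    """A confounding parameter could not be extracted from metadata."""


class ConfigurationError(T1StdError):
    """An invalid pipeline/binning configuration or an untrainable setup
    (e.g. no reference-matching record, empty bin)."""


class ApplicationError(T1StdError):
    """Standardisation cannot be applied, e.g. ensemble mode meeting a
    category absent from the training codebook."""


class ArchiveError(T1StdError):
    """A pipeline archive is corrupt, truncated or of an unsupported
    format version."""
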