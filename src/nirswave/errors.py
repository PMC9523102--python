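"""Exception hierarchy shared across the pipeline stages."""


class NirswaveError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NirswaveError):
    """A file does not conform to the expected on-disk layout."""


class MontageError(NirswaveError):
    """Recording content is inconsistent with the probe montage."""


class DataQualityError(NirswaveError):
    """Signal quality is insufficient for the requested analysis."""


class DomainError(NirswaveError):
    """An argument is outside its documented domain."""


class PreprocessingError(NirswaveError):
    """A preprocessing stage cannot be applied to the given series."""


class ConfigurationError(NirswaveError):
    """A configuration value violates its invariants."""


class DegenerateDataError(NirswaveError):
    """A statistic is undefined for the given data (e.g. zero variance)."""
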