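"""Exception hierarchy shared across the package."""


class PrdmscanError(Exception):
    """Base class for all package-specific errors."""


class MafFormatError(PrdmscanError):
    """A MAF-dialect table is malformed (e.g. a mandatory column is missing)."""


class ValidationError(PrdmscanError):
    """A value violates a documented invariant (e.g. a score outside [0, 1])."""


class ConfigurationError(PrdmscanError):
    """Inconsistent or incomplete configuration (e.g. a cohort missing from the catalog)."""


class DomainInputError(PrdmscanError):
    """An operation was called on input outside its domain (e.g. zero patients)."""


class NormalizationError(PrdmscanError):
    """A count matrix cannot be normalized (e.g. an all-zero library)."""


class ScanError(PrdmscanError):
    """The driver scan cannot proceed (e.g. degenerate background)."""
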