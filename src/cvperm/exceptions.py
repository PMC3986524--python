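"""Exception hierarchy shared by all cvperm modules."""


class CvpermError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CvpermError):
    """Invalid or inconsistent inference descriptor."""


class PluginError(ConfigError):
    """A DYNAMIC_IMPORT:: reference could not be resolved."""


class DataError(CvpermError):
    """Problem with the input data (format, alignment, domain)."""


class FormatError(DataError):
    """A cell or file does not conform to the expected dialect."""


class AlignmentError(DataError):
    """Subject identifiers cannot be aligned across input files."""


class DegenerateDataError(DataError):
    """Data degenerate for the requested computation (zero variance,
    n too small, fully-missing column, ...)."""


class IntegrityError(CvpermError):
    """A reduce step received conflicting or duplicate results."""


class RunInterrupted(CvpermError):
    """An inference run stopped before completion; the ledger on disk
    can be used to resume it."""
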