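"""Exception hierarchy for the track-classification pipeline."""


class IpsProgError(Exception):
    """Base class for all package-specific errors."""


class FormatError(IpsProgError):
    """A CSV or config file does not have the expected shape."""


class IntegrityError(IpsProgError):
    """Conflicting duplicate records for the same (cell, frame, feature)."""


class CoordinateError(IpsProgError):
    """A time or frame does not lie on the recording grid."""


class ConfigError(IpsProgError):
    """An invalid simulation or imputation configuration."""


class ImputationError(IpsProgError):
    """Imputation requested on a window with no observed values."""


class EmptyDatasetError(IpsProgError):
    """A window yields no eligible cells."""


class StratificationError(IpsProgError):
    """A class-stratified operation received a class with no members."""


class SelectionError(IpsProgError):
    """Window or feature selection could not produce a result."""


class TrainingError(IpsProgError):
    """Model training preconditions violated (e.g. single-class data)."""


class ProtocolError(IpsProgError):
    """A validation protocol guard was violated."""
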