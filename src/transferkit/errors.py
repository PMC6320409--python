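"""Exception hierarchy shared across the package."""


class TransferKitError(Exception):
    """Base class for all package errors."""


class ParseError(TransferKitError):
    """A signal or annotation file could not be parsed."""


class ConfigError(TransferKitError):
    """Invalid configuration or parameter combination."""


class SegmentationError(TransferKitError):
    """A window could not be cut from a recording."""


class DegenerateSignalError(TransferKitError):
    """A signal is too short, constant, or otherwise unusable for an operation."""
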