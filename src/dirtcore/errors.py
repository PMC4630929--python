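"""Exception taxonomy shared by all pipeline stages."""


class DirtError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(DirtError):
    """An external file could not be read or written in the expected format."""


class InvalidInputError(DirtError, ValueError):
    """An argument violates a documented precondition."""


class ConsistencyError(DirtError):
    """Internally inconsistent data, e.g. a trait record referencing an unknown trait id."""


class NoRootError(DirtError):
    """No connected component in the scene is eligible as the root."""


class ConfigError(DirtError, ValueError):
    """One or more configuration values are out of range."""
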