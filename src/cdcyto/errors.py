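"""Exception hierarchy for cdcyto."""


class CdcytoError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CdcytoError):
    """Invalid configuration value (non-positive dimension, bad offsets, ...)."""


class InputError(CdcytoError):
    """Invalid runtime input (empty frame sequence, shape mismatch, ...)."""


class SchemaError(CdcytoError):
    """Tabular input does not match the documented record schema."""


class SequencingError(CdcytoError):
    """Frames or detections presented out of temporal order."""


class DataIntegrityError(CdcytoError):
    """Measured quantities violate a structural invariant (e.g. exit before entry)."""


class AmbiguityError(CdcytoError):
    """An observation cannot be attributed unambiguously (overlapping regions)."""
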