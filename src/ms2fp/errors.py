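"""Exception hierarchy for the spectrum-to-fingerprint pipeline."""


class Ms2fpError(Exception):
    """Base class for all package errors."""


class MspFormatError(Ms2fpError):
    """A malformed record in an .msp stream (carries the block index)."""

    def __init__(self, message: str, block_index: int | None = None):
        super().__init__(message)
        self.block_index = block_index


class StructureError(Ms2fpError):
    """A SMILES/InChI string could not be parsed into a molecule."""


class AnnotationError(Ms2fpError):
    """A spectrum carries neither custom fingerprint bits nor a parsable structure."""


class DimensionError(Ms2fpError):
    """Mismatched dimensions (fingerprint lengths, aligned sequences)."""


class DegenerateSpectrumError(Ms2fpError):
    """A spectrum with no usable intensity mass (all-zero or empty after filtering)."""


class TokenizationError(Ms2fpError):
    """A value required to be inside the token vocabulary falls outside it."""


class DecodeError(Ms2fpError):
    """A decoder token sequence violates the target grammar."""


class ConfigError(Ms2fpError):
    """An invalid or missing configuration value (names the offending key)."""


class CheckpointError(Ms2fpError):
    """A checkpoint file is unreadable or incompatible with the configuration."""
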