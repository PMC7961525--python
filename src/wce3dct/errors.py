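"""Exception hierarchy for the codec."""


class Wce3dctError(Exception):
    """Base class for all codec errors."""


class InputShapeError(Wce3dctError, ValueError):
    """An array has the wrong shape, dtype range, or dimensions."""


class ConfigurationError(Wce3dctError, ValueError):
    """An invalid parameter or configuration value."""


class EncodingRangeError(Wce3dctError, ValueError):
    """A value exceeds the range representable by the entropy code."""


class BitstreamError(Wce3dctError, ValueError):
    """Base class for malformed-bitstream errors."""


class BadMagicError(BitstreamError):
    """The stream does not start with the expected magic bytes."""


class TruncatedStreamError(BitstreamError):
    """The stream ended before decoding completed."""


class InvalidCodeError(BitstreamError):
    """A bit pattern does not correspond to any Huffman code."""


class PipelineError(Wce3dctError, RuntimeError):
    """A codec stage received inconsistent intermediate state."""
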