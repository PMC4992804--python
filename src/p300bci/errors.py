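"""Exception hierarchy for the P300 BCI pipeline."""


class P300Error(Exception):
    """Base class for package errors."""


class InvalidParameterError(P300Error, ValueError):
    """A parameter is outside its documented domain."""


class LengthError(P300Error, ValueError):
    """A signal or vector has the wrong length for the requested operation."""


class ChannelError(P300Error, KeyError):
    """A required channel label is missing from a recording."""


class FormatError(P300Error, ValueError):
    """A file does not parse under the documented dialect."""


class ModelFormatError(FormatError):
    """A stored network model is truncated or internally inconsistent."""
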