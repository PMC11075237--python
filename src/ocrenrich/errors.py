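"""Exception hierarchy for ocrenrich."""


class OcrEnrichError(Exception):
    """Base class for all package errors."""


class InputError(OcrEnrichError):
    """Fatal problem with user-supplied input files or folders."""


class ParameterError(OcrEnrichError):
    """A run option is outside its valid domain."""


class ConsistencyError(OcrEnrichError):
    """Internal disagreement between overlap counting and window statistics."""
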