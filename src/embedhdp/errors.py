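"""Exception hierarchy.

Every failure mode named by the library contracts maps to a distinct
exception class so batch callers can distinguish bad input from model
degeneracies without string matching.
"""


class EmbedHdpError(Exception):
    """Base class for all library errors."""


class InvalidInputError(EmbedHdpError, ValueError):
    """Empty or malformed caller input (empty sentence, bad parameter value)."""


class ConfigurationError(EmbedHdpError, ValueError):
    """An unusable configuration (e.g. embedding dimension < 2, missing model)."""


class MissingAnalyzerError(ConfigurationError):
    """Morphological mode requested but no analyzer adapter is available."""


class DegenerateDocumentError(EmbedHdpError):
    """A sentence quantized to an empty pseudo-Bag-of-Words document."""


class DictionaryMismatchError(EmbedHdpError):
    """A document references a term id outside the fitted dictionary."""


class DegenerateDistributionError(EmbedHdpError):
    """A zero topic-distribution vector where a direction is required."""


class SchemaError(EmbedHdpError, ValueError):
    """A dataset file is missing required columns or is empty."""


class MalformedRowError(EmbedHdpError, ValueError):
    """Dataset rows failed validation; the message lists 1-based line numbers."""


class UndefinedCorrelationError(EmbedHdpError):
    """Correlation is undefined (zero variance or too few points)."""
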