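"""Exception hierarchy.

Every error raised by the package derives from :class:`PromshapeError`, so
callers (and the CLI) can separate domain failures from programming errors.
"""


class PromshapeError(Exception):
    """Base class for all package errors."""


class ParseError(PromshapeError):
    """A record in an input file could not be parsed."""


class ContractError(PromshapeError):
    """An argument violated a documented precondition."""


class ConfigurationError(PromshapeError):
    """A configuration object is inconsistent or incomplete."""


class BoundaryError(PromshapeError):
    """A sequence window would overrun a contig boundary."""


class GenomeLookupError(PromshapeError):
    """A chromosome is absent from the reference."""


class ReferenceMismatchError(PromshapeError):
    """The declared ref allele does not match the reference genome."""


class SchemaError(PromshapeError):
    """A feature matrix does not match the expected schema."""


class CapacityError(PromshapeError):
    """A sampling request exceeds the available space."""


class UndefinedMetricError(PromshapeError):
    """A metric is undefined for the given inputs (e.g. single-class labels)."""


class CompletenessError(PromshapeError):
    """A lookup table is missing required entries."""
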