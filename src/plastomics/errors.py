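"""Exception hierarchy shared across the package."""


class PlastomicsError(Exception):
    """Base class for all package errors."""


class ParseError(PlastomicsError):
    """A file could not be parsed under the requested format."""


class ValidationError(PlastomicsError):
    """An object violates one of its structural invariants."""


class SizingError(PlastomicsError):
    """A requested region is too small for the content it must hold."""


class AnchorResolutionError(PlastomicsError):
    """An inversion anchor is absent or ambiguous in the record."""


class LookupError_(PlastomicsError):
    """A named gene is missing from a record."""


class AmbiguityError(PlastomicsError):
    """A name resolves to more than one single-copy feature."""


class MarkerSetError(PlastomicsError):
    """Marker sets of compared genomes are missing/duplicated markers."""


class PartitionError(PlastomicsError):
    """No inverted-repeat pair could be found at the given threshold."""


class ConfigError(PlastomicsError):
    """A configuration value is outside its allowed range."""
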