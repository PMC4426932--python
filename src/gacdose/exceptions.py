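"""Exception hierarchy shared across the pipeline."""


class GacdoseError(Exception):
    """Base class for all package errors."""


class ValidationError(GacdoseError, ValueError):
    """An input object violates a documented invariant."""


class FormatError(GacdoseError, ValueError):
    """A file does not conform to the expected dialect/standard tags."""


class GeometryError(GacdoseError, ValueError):
    """A geometric operation is undefined (e.g. point at or behind the source)."""


class DetectionError(GacdoseError, RuntimeError):
    """A signal feature (edge, half-maximum crossing) could not be found."""


class FitError(GacdoseError, RuntimeError):
    """A regression cannot be performed (degenerate data)."""


class TableLookupError(GacdoseError, KeyError):
    """A lookup-table query references an unknown leaf or angle."""


class ConfigurationError(GacdoseError, ValueError):
    """A required configuration element (e.g. the reference angle) is missing."""
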