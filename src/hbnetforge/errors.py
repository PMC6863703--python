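"""Exception hierarchy."""


class HBNetForgeError(Exception):
    """Base class for all package errors."""


class ParseError(HBNetForgeError):
    """Malformed content in an otherwise readable file."""


class FormatError(HBNetForgeError):
    """File is not in a supported/expected format."""


class ValidationError(HBNetForgeError):
    """A domain object violates one of its invariants."""


class SpecError(HBNetForgeError):
    """An active-site specification requests something impossible."""


class GeometryError(HBNetForgeError):
    """Degenerate or physically impossible geometry."""


class ConstructionError(HBNetForgeError):
    """A synthetic fixture could not be built (e.g. overlapping segments)."""
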