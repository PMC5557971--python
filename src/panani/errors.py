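"""Exception hierarchy shared across the package."""


class PananiError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PananiError):
    """A file is structurally invalid (wrong columns, malformed line...)."""


class ValidationError(PananiError):
    """Parsed content violates a domain invariant (coordinates, symmetry...)."""


class ConfigError(PananiError):
    """A configuration object is internally contradictory."""


class InputError(PananiError):
    """A function argument is outside its documented domain."""
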