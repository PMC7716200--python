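"""Exception hierarchy shared by all pipeline stages."""


class LpevalError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(LpevalError):
    """An invalid configuration value; always names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class AlignmentError(LpevalError):
    """Site coordinates of two inputs do not line up 1:1."""


class PedigreeError(LpevalError):
    """Pedigree is malformed (cycle, missing parent row, ...)."""


class VcfParseError(LpevalError):
    """A VCF record could not be parsed."""
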