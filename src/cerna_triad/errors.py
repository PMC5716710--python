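"""Exception hierarchy shared across the package."""


class CernaTriadError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CernaTriadError, ValueError):
    """An option or configuration field is outside its documented domain."""


class ValidationError(CernaTriadError, ValueError):
    """A domain object violates one of its invariants."""


class ParseError(CernaTriadError, ValueError):
    """An input file could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class DegenerateInputError(CernaTriadError, ValueError):
    """A computation is undefined for the given input (e.g. constant vector)."""
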