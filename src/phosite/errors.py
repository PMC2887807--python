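"""Exception hierarchy shared by the package and mapped to CLI exit codes."""


class PhositeError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(PhositeError):
    """Invalid configuration value (window size, ratio factor, ...)."""

    exit_code = 2


class DataError(PhositeError):
    """Invalid or inconsistent input data (parse and validation failures)."""

    exit_code = 3


class ParseError(DataError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ModelError(PhositeError):
    """Missing, mismatched or corrupt model bundle."""

    exit_code = 4
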