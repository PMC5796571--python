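"""Exception hierarchy for qlloq."""


class QlloqError(Exception):
    """Base class for package errors."""


class SchemaError(QlloqError):
    """A required input column is missing or the schema is inconsistent."""


class RowParseError(QlloqError):
    """A data cell could not be parsed; carries the 1-based file line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class InsufficientDataError(QlloqError):
    """Too few usable calibrator points for the requested operation."""


class InvalidFitError(QlloqError):
    """An operation required a converged calibration fit but got none."""
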