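"""Exception hierarchy shared across the package."""

from __future__ import annotations


class EsaceaError(Exception):
    """Base class for all package errors."""


class ValidationError(EsaceaError, ValueError):
    """An input violates a documented precondition or invariant."""


class UndefinedRateError(EsaceaError, ZeroDivisionError):
    """A rate or ratio is requested with a zero denominator."""


class CurrencyError(EsaceaError, ValueError):
    """A money amount is in the wrong currency for the requested operation."""


class CohortParseError(EsaceaError, ValueError):
    """A cohort CSV row could not be parsed; carries the 1-based data row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class ConfigError(EsaceaError, ValueError):
    """Model configuration is invalid; collects every violation found."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))
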