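"""Exception hierarchy and aggregated validation reporting."""

from __future__ import annotations

from collections.abc import Iterable


class FuzzyGrantError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FuzzyGrantError, ValueError):
    """A schema, profile or bounds definition is internally inconsistent."""


class DegenerateWishError(ConfigurationError):
    """An investor wish fuzzifies to zero, so the term breakpoints collapse.

    Every linguistic-term formula divides by the fuzzified wish alpha; a wish
    at or below the group's minimum possible sum is therefore rejected.
    """


class ValidationError(FuzzyGrantError, ValueError):
    """Input data failed validation; carries every issue found, not just the first."""

    def __init__(self, issues: Iterable[str] | str):
        if isinstance(issues, str):
            issues = [issues]
        self.issues: list[str] = list(issues)
        super().__init__("; ".join(self.issues) or "validation failed")


class ValidationReport:
    """Collects validation issues so callers can report them all at once."""

    def __init__(self) -> None:
        self.issues: list[str] = []

    def add(self, message: str) -> None:
        self.issues.append(message)

    def extend(self, messages: Iterable[str]) -> None:
        self.issues.extend(messages)

    def __bool__(self) -> bool:
        return bool(self.issues)

    def raise_if_any(self) -> None:
        if self.issues:
            raise ValidationError(self.issues)
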