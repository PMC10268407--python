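"""Exception hierarchy shared across the package."""


class DectRespError(Exception):
    """Base class for all package errors."""


class DomainError(DectRespError):
    """A numeric argument is outside the rule's domain (e.g. baseline <= 0)."""


class EvaluabilityError(DectRespError):
    """A patient/timepoint cannot be assessed under a criterion's gate."""


class SchemaError(DectRespError):
    """A table is missing required columns or is otherwise malformed."""


class RowError(DectRespError):
    """One or more rows violate field-level invariants.

    ``problems`` is a list of ``(line_number, message)`` pairs; line numbers
    are 1-based and count the header row.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        msgs = "; ".join(f"line {ln}: {msg}" for ln, msg in self.problems)
        super().__init__(msgs)


class IntegrityError(DectRespError):
    """Cross-row integrity violation (duplicate keys, overlapping lines)."""
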