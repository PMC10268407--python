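"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

from .errors import DomainError

#: Mean Gregorian month length in days; all month conversions use this so
#: durations are bit-exact across modules.
MONTH_DAYS = 30.4375


def days_to_months(days: float) -> float:
    return days / MONTH_DAYS


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (decimal ROUND_HALF_UP semantics).

    Python's builtin ``round`` is banker's rounding; reported percentages in
    this package round 0.5 away from zero instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


def percent_change(baseline: float, followup: float) -> float:
    """Signed percent change 100 * (followup - baseline) / baseline.

    Full precision is retained; rounding happens only in reporting layers.
    """
    if baseline <= 0:
        raise DomainError(f"baseline must be > 0, got {baseline!r}")
    if followup < 0:
        raise DomainError(f"followup must be >= 0, got {followup!r}")
    return 100.0 * (followup - baseline) / baseline
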