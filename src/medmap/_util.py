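"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` half-up to ``ndigits`` decimals.

    Python's built-in ``round`` is banker's rounding; printed percentage
    tables in terminology-mapping reports conventionally round half-up
    (e.g. 1.5 % prints as 1.50, 2.665 as 2.67).
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(quantum, rounding=ROUND_HALF_UP))


def normalize_term(s: str) -> str:
    """Case-fold and collapse internal whitespace for string cross-checks."""
    return " ".join(s.casefold().split())
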