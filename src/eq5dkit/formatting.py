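"""Report-formatting helpers: half-up rounding and journal-style p-values."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "format_p"]


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (0.5 -> 1), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def format_p(p: float) -> str:
    """Journal-style p-value string: ``"<.001"``, ``".002"``, ``".19"``."""
    if p < 0.001:
        return "<.001"
    if p < 0.01:
        text = f"{round_half_up(p, 3):.3f}"
    else:
        text = f"{round_half_up(p, 2):.2f}"
    return text.lstrip("0")
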