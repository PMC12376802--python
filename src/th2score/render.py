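"""Half-up decimal rendering used for every human-facing number.

Centralised so that printed-format conventions (one-decimal percentages,
one-decimal likelihood ratios, integer prevalence) are testable in one place.
"""

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "fmt_pct", "fmt_ratio"]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round ``x`` to ``decimals`` places, ties away from zero upward.

    Uses the shortest-repr decimalisation of the float so values such as
    ``96.15`` round to ``96.2`` rather than being bitten by binary
    representation error.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def fmt_pct(p: float, decimals: int = 1) -> str:
    """Render a proportion in [0, 1] as a percentage string, half-up."""
    v = round_half_up(p * 100.0, decimals)
    if decimals == 0:
        return f"{int(v)}%"
    return f"{v:.{decimals}f}%"


def fmt_ratio(r: float, decimals: int = 1) -> str:
    """Render a likelihood ratio (or any plain ratio) half-up."""
    return f"{round_half_up(r, decimals):.{decimals}f}"
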