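"""Percentage/ratio reporting helpers.

Reported percentages use round-half-up at one decimal by default; a
"truncate" mode is provided because published catalogues sometimes floor
their percentages (e.g. 467/1499 = 31.15% printed as 31.1%).
"""

from __future__ import annotations

from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

ROUNDING_MODES = ("half_up", "truncate")


def round_report(value: float, ndigits: int = 1, mode: str = "half_up") -> float:
    """Round `value` to `ndigits` decimals for reporting."""
    if mode not in ROUNDING_MODES:
        raise ValueError(f"unknown rounding mode {mode!r}")
    quant = Decimal(1).scaleb(-ndigits)
    rounding = ROUND_HALF_UP if mode == "half_up" else ROUND_DOWN
    return float(Decimal(repr(value)).quantize(quant, rounding=rounding))


def pct(numerator: float, denominator: float, ndigits: int = 1,
        mode: str = "half_up") -> float:
    """100 * numerator / denominator, rounded for reporting."""
    return round_report(100.0 * numerator / denominator, ndigits, mode)
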