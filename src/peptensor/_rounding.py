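"""Half-up rounding helpers matching tabulated print precision."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero up, as printed tables do (2.5 -> 3)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
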