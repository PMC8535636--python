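"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at the given decimal place.

    Operates on the shortest decimal representation of ``x`` so that values
    like 0.925 (not exactly representable in binary) round to 0.93, matching
    how tabulated rates are conventionally printed.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))
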