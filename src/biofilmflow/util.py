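"""Small shared helpers."""

from __future__ import annotations

import math


def round_sig(x: float, n: int = 2) -> float:
    """Round ``x`` to ``n`` significant figures (half away from zero)."""
    if x == 0 or not math.isfinite(x):
        return x
    ndigits = n - 1 - math.floor(math.log10(abs(x)))
    # round-half-away-from-zero, so 0.675 Pa -> 0.68 Pa regardless of binary repr
    scale = 10.0**ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x > 0 else -1)
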