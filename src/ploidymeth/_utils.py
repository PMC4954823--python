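"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as percentages are reported."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(numer: float, denom: float, ndigits: int = 1) -> float:
    """numer/denom as a percentage, rounded half-up to ``ndigits``."""
    if denom <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(100.0 * numer / denom, ndigits)


def substream(seed: int, *stream: int) -> np.random.Generator:
    """Independent, reproducible generator for one stage/sample."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *stream]))
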