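"""Small shared helpers: deterministic rounding and seeded RNG streams."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention used for every reported percentage)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, ndigits: int = 1) -> float:
    if denominator <= 0:
        raise ValueError("percent undefined for a non-positive denominator")
    return round_half_away(100.0 * numerator / denominator, ndigits)


def stream(*key: int) -> np.random.Generator:
    """One independent pseudorandom stream per integer key tuple.

    Keyed streams keep the simulator stable under composition: adding a
    chromosome or a condition never perturbs the draws of another.
    """
    return np.random.default_rng(list(key))
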