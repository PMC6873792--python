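"""Small shared helpers: rounding conventions and deterministic RNG derivation."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

NA_REP = "NA"


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (0.5 -> 1), as in hand-reported percentages.

    Python's built-in ``round`` uses banker's rounding, which would turn e.g.
    56.5% into 56%; reported fractions here follow the half-up convention.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float) -> int:
    """Integer percent, half-up."""
    if denominator == 0:
        raise ValueError("percent undefined for zero denominator")
    return int(round_half_up(100.0 * numerator / denominator))


def rng_from(seed: int, *salt: int) -> np.random.Generator:
    """Derive an independent generator from a base seed and integer salts.

    Keeps sub-streams (universe, LFQ noise, sampling, folds) decoupled so
    changing one stage's draws never perturbs another's.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *salt]))
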