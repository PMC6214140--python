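"""Small shared helpers (rounding, seeding)."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero.

    Python's built-in ``round`` is banker's rounding; published percentage
    tables conventionally use half-up (2.25 -> 2.3 at one decimal), so all
    reported percentages go through this helper.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def child_seeds(seed: int | None, n: int) -> list[np.random.SeedSequence]:
    """Expand one user-facing seed into ``n`` independent child streams."""
    return np.random.SeedSequence(seed).spawn(n)
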