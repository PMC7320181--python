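"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def _round_scalar(x: float, ndigits: int) -> float:
    d = Decimal(repr(float(x)))
    # absorb sub-ulp accumulation noise (e.g. a mean of many terms landing
    # at ...54999999999 instead of ...55) before the printed rounding
    d = d.quantize(Decimal(1).scaleb(-(ndigits + 8)), rounding=ROUND_HALF_UP)
    quantum = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(quantum, rounding=ROUND_HALF_UP))


def round_half_up(x, ndigits: int = 0):
    """Round decimal ties away from zero toward +inf (half-up).

    Python's built-in ``round`` is banker's rounding; printed summary
    tables here use conventional half-up so that e.g. 0.35 -> 0.4 at one
    decimal. Operates on the shortest decimal representation of the
    value (via ``repr``), pre-quantized 8 digits below the target so
    decimal ties behave as written rather than as their binary
    approximations. Works on scalars and numpy arrays; only intended
    for formatting, not bulk numerics.
    """
    if np.isscalar(x):
        return _round_scalar(x, ndigits)
    arr = np.asarray(x, dtype=float)
    return np.array([_round_scalar(v, ndigits) for v in arr.ravel()]
                    ).reshape(arr.shape)
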