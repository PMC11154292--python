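"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-derivations (sorting, enumeration, direct
ANOVA algebra) kept free of the implementation code paths they check.
"""

from __future__ import annotations

import numpy as np


def median_by_sorting(values) -> float:
    """Median as sort-and-index with the midpoint convention."""
    v = sorted(float(x) for x in values)
    n = len(v)
    if n == 0:
        raise ValueError("empty")
    if n % 2 == 1:
        return v[n // 2]
    return 0.5 * (v[n // 2 - 1] + v[n // 2])


def darkest_of_thickest(lesions) -> int:
    """Hand-enumerated plaque-GSM selection rule.

    ``lesions`` is a list of (side, imt_mm, calibrated_gsm) tuples; returns
    the index of the winner: per side the thickest lesion (thickness tie ->
    lower GSM), across sides the lower GSM (GSM tie -> left).
    """
    eligible = [(i, s, t, g) for i, (s, t, g) in enumerate(lesions) if t >= 1.5]
    if not eligible:
        raise LookupError("no plaque")
    winners = {}
    for i, s, t, g in eligible:
        if s not in winners:
            winners[s] = (i, t, g)
        else:
            _, t0, g0 = winners[s]
            if t > t0 or (t == t0 and g < g0):
                winners[s] = (i, t, g)
    best = None
    for side in ("left", "right"):  # left first breaks GSM ties
        if side in winners:
            i, t, g = winners[side]
            if best is None or g < best[1]:
                best = (i, g)
    return best[0]


def icc_oneway(a: np.ndarray, b: np.ndarray) -> float:
    """One-way random-effects single-measure ICC from raw ANOVA sums."""
    x = np.column_stack([a, b]).astype(float)
    n, k = x.shape
    grand = x.mean()
    ss_between = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_within = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum()
    msb = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)
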