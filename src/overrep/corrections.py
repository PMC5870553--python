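"""Multiple-testing corrections: Bonferroni, Benjamini-Hochberg,
Benjamini-Yekutieli.

An enrichment run produces one raw p-value per eligible term, so the
number of hypotheses ``m`` is the number of terms actually tested (those
carried by at least two background items by default), not the vocabulary
size.  ``m`` can be passed explicitly when the supplied vector is a slice
of a larger family.

All three procedures return adjusted p-values in the original order,
capped at 1:

* Bonferroni controls the family-wise error rate: ``q_i = min(1, m p_i)``.
* Benjamini-Hochberg (BH) controls the FDR under independence or positive
  dependence via the step-up rule ``q_(i) = p_(i) m / i`` followed by a
  cumulative minimum from the largest rank downward.
* Benjamini-Yekutieli (BY) multiplies the BH quantities by the harmonic
  number ``c(m) = sum_{j<=m} 1/j``, buying validity under arbitrary
  dependence at the price of power; hence Bonferroni >= BY >= BH holds
  elementwise for every input.
"""

from __future__ import annotations

import numpy as np

__all__ = ["bonferroni", "bh_fdr", "by_fdr", "CORRECTIONS", "adjust"]


def _validated(p, m: int | None) -> tuple[np.ndarray, int]:
    arr = np.asarray(p, dtype=np.float64)
    if arr.ndim != 1:
        raise ValueError("p-value vector must be one-dimensional")
    if arr.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(arr <= 0.0) or np.any(arr > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    if m is None:
        m = arr.size
    elif m < arr.size:
        raise ValueError(
            f"hypothesis count m={m} smaller than vector length {arr.size}"
        )
    return arr, m


def bonferroni(p, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values, ``min(1, m * p_i)``."""
    arr, m = _validated(p, m)
    return np.minimum(arr * m, 1.0)


def bh_fdr(p, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR-adjusted p-values."""
    arr, m = _validated(p, m)
    order = np.argsort(arr, kind="stable")
    ranked = arr[order] * m / np.arange(1, arr.size + 1)
    # enforce monotonicity from the largest rank downward
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def by_fdr(p, m: int | None = None) -> np.ndarray:
    """Benjamini-Yekutieli FDR-adjusted p-values (BH with harmonic penalty)."""
    arr, m = _validated(p, m)
    c_m = float(np.sum(1.0 / np.arange(1, m + 1)))
    order = np.argsort(arr, kind="stable")
    ranked = arr[order] * m * c_m / np.arange(1, arr.size + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


CORRECTIONS = {
    "bonferroni": bonferroni,
    "bh": bh_fdr,
    "by": by_fdr,
}


def adjust(method: str, p, m: int | None = None) -> np.ndarray:
    """Apply a correction by name; ``"none"`` returns the input unchanged."""
    if method == "none":
        arr, _ = _validated(p, m)
        return arr
    try:
        fn = CORRECTIONS[method]
    except KeyError:
        raise ValueError(
            f"unknown correction {method!r}; valid: none, "
            + ", ".join(CORRECTIONS)
        ) from None
    return fn(p, m)
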