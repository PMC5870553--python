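"""Exact one-sided tests on a 2x2 item/term contingency.

All three tests consume the same sufficient statistics ``(k, n, K, N)``:
``k`` query items carrying the term, out of a query of ``n`` matched
items, against ``K`` carriers among ``N`` background items.

* ``fisher_one_sided`` — the one-sided Fisher exact test; its p-value is
  the hypergeometric tail ``P(X >= k)`` (over-representation) or
  ``P(X <= k)`` (under-representation) with ``X ~ Hypergeom(N, K, n)``.
* ``hypergeom_test`` — exposed as a distinct test name for output parity
  with classical enrichment tools, but mathematically identical to the
  one-sided Fisher test on a 2x2 table; it delegates to it, bit for bit.
* ``binomial_test`` — the binomial approximation: ``n`` independent
  draws with success probability ``K/N``.

Everything is computed in log space through a dynamically grown
log-factorial buffer, so tables at proteome scale (``N`` in the tens of
thousands) neither overflow nor lose the small tail probabilities that
make enrichment analysis useful.  Tail sums start at the extreme
(smallest-probability) end of the support and accumulate with compensated
summation.  A result cache keyed by ``(test, direction, k, n, K, N)``
makes bulk analysis cheap: random query sets against one background keep
hitting the same handful of contingency configurations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Contingency",
    "LogFactorialBuffer",
    "ResultCache",
    "log_factorial",
    "hypergeom_pmf",
    "fisher_one_sided",
    "hypergeom_test",
    "binomial_test",
    "cached_test",
    "TESTS",
    "DIRECTIONS",
]

DIRECTIONS = ("over", "under")

#: Smallest positive double; p-values are clamped here rather than
#: underflowing to an exact zero (a reported p of 0 is a lie).
_TINY = 5e-324


@dataclass(frozen=True)
class Contingency:
    """Sufficient statistics of one term x one query set.

    Attributes
    ----------
    k:
        Query items annotated with the term.
    n:
        Query size after matching to the background.
    K:
        Background items annotated with the term.
    N:
        Background size.
    """

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self):
        if self.N < 1:
            raise ValueError(f"contingency requires N >= 1, got N={self.N}")
        if not 1 <= self.n <= self.N:
            raise ValueError(
                f"contingency requires 1 <= n <= N, got n={self.n}, N={self.N}"
            )
        if not 1 <= self.K <= self.N:
            raise ValueError(
                f"contingency requires 1 <= K <= N, got K={self.K}, N={self.N}"
            )
        lo, hi = self.support
        if not lo <= self.k <= hi:
            raise ValueError(
                f"contingency requires max(0, n+K-N) <= k <= min(n, K): "
                f"k={self.k} outside [{lo}, {hi}]"
            )

    @property
    def support(self) -> tuple[int, int]:
        """Inclusive bounds of the hypergeometric support for these margins."""
        return max(0, self.n + self.K - self.N), min(self.n, self.K)


class LogFactorialBuffer:
    """Append-only table of ln(i!), grown on demand with amortised doubling.

    Entry ``i`` holds ``ln(i!)`` in nats; the recurrence
    ``values[i] = values[i-1] + ln(i)`` keeps successive entries exactly
    consistent, which the tail sums rely on for cancellation-free
    log-binomial coefficients.
    """

    __slots__ = ("_values", "_filled")

    def __init__(self, initial_capacity: int = 1024):
        self._values = np.zeros(max(1, initial_capacity))
        self._filled = 1  # ln(0!) = 0 is always present

    def __len__(self) -> int:
        return self._filled

    def __call__(self, m: int) -> float:
        """Return ln(m!), extending the buffer if needed."""
        if m < 0:
            raise ValueError(f"log-factorial of negative argument: {m}")
        if m >= self._filled:
            self._extend(m)
        return float(self._values[m])

    def _extend(self, m: int) -> None:
        capacity = len(self._values)
        if m >= capacity:
            new_capacity = max(2 * capacity, m + 1)
            grown = np.zeros(new_capacity)
            grown[:capacity] = self._values
            self._values = grown
        lo = self._filled
        steps = np.log(np.arange(lo, m + 1, dtype=np.float64))
        self._values[lo:m + 1] = self._values[lo - 1] + np.cumsum(steps)
        self._filled = m + 1


#: Shared buffer used when a caller does not pass its own.
_DEFAULT_BUFFER = LogFactorialBuffer()


def log_factorial(m: int, buffer: LogFactorialBuffer | None = None) -> float:
    """ln(m!) in nats, via the (shared or supplied) log-factorial buffer."""
    return (buffer or _DEFAULT_BUFFER)(m)


def _log_choose(n: int, k: int, lf: LogFactorialBuffer) -> float:
    return lf(n) - lf(k) - lf(n - k)


def _check_direction(direction: str) -> None:
    if direction not in DIRECTIONS:
        raise ValueError(
            f"direction must be one of {DIRECTIONS}, got {direction!r}"
        )


def _log_hyper_pmf(c: Contingency, x: int, lf: LogFactorialBuffer) -> float:
    return (
        _log_choose(c.K, x, lf)
        + _log_choose(c.N - c.K, c.n - x, lf)
        - _log_choose(c.N, c.n, lf)
    )


def hypergeom_pmf(c: Contingency, x: int,
                  buffer: LogFactorialBuffer | None = None) -> float:
    """P(X = x) for X ~ Hypergeom(N, K, n); 0 outside the support."""
    lo, hi = c.support
    if not lo <= x <= hi:
        return 0.0
    lf = buffer or _DEFAULT_BUFFER
    return math.exp(_log_hyper_pmf(c, x, lf))


def _tail_from_logs(logs: list[float]) -> float:
    """Sum exp(logs) stably: factor out the maximum, compensate the rest."""
    peak = max(logs)
    total = math.fsum(math.exp(lp - peak) for lp in logs)
    p = math.exp(peak + math.log(total))
    if p <= 0.0:
        return _TINY
    return min(p, 1.0)


def fisher_one_sided(c: Contingency, direction: str = "over",
                     buffer: LogFactorialBuffer | None = None) -> float:
    """One-sided Fisher exact p-value (the hypergeometric tail).

    ``over`` returns P(X >= k), ``under`` returns P(X <= k).  The tail is
    accumulated from the extreme end of the support inward so that the
    smallest terms are added first.
    """
    _check_direction(direction)
    lf = buffer or _DEFAULT_BUFFER
    lo, hi = c.support
    if direction == "over":
        if c.k <= lo:
            return 1.0
        xs = range(hi, c.k - 1, -1)
    else:
        if c.k >= hi:
            return 1.0
        xs = range(lo, c.k + 1)
    return _tail_from_logs([_log_hyper_pmf(c, x, lf) for x in xs])


def hypergeom_test(c: Contingency, direction: str = "over",
                   buffer: LogFactorialBuffer | None = None) -> float:
    """Hypergeometric tail test; identical to `fisher_one_sided` by definition.

    The one-sided Fisher exact test on a 2x2 table *is* the hypergeometric
    tail probability, so this delegates; both names are kept because
    enrichment tools conventionally list them as separate tests.
    """
    return fisher_one_sided(c, direction, buffer)


def binomial_test(c: Contingency, direction: str = "over",
                  buffer: LogFactorialBuffer | None = None) -> float:
    """One-sided binomial tail with success probability K/N.

    Approximates the exact test by sampling query membership with
    replacement; converges to the hypergeometric tail as N grows with
    K/N held fixed.
    """
    _check_direction(direction)
    lf = buffer or _DEFAULT_BUFFER
    p = c.K / c.N
    if p >= 1.0:
        # every background item carries the term: X = n almost surely
        if direction == "over":
            return 1.0
        return 1.0 if c.k >= c.n else _TINY
    log_p, log_q = math.log(p), math.log1p(-p)

    def log_pmf(x: int) -> float:
        return _log_choose(c.n, x, lf) + x * log_p + (c.n - x) * log_q

    if direction == "over":
        if c.k <= 0:
            return 1.0
        xs = range(c.n, c.k - 1, -1)
    else:
        if c.k >= c.n:
            return 1.0
        xs = range(0, c.k + 1)
    return _tail_from_logs([log_pmf(x) for x in xs])


#: Test identifier -> implementation; the identifiers are the names used
#: in configuration, CLI flags and report columns.
TESTS = {
    "fisher": fisher_one_sided,
    "hypergeometric": hypergeom_test,
    "binomial": binomial_test,
}


class ResultCache:
    """Memo table for p-values keyed by (test, direction, k, n, K, N).

    Purely an accelerator: a cached value is bit-identical to
    recomputation, so enabling or disabling the cache can never change a
    result.  Hit/miss counters are kept for logging in bulk runs.
    """

    __slots__ = ("_store", "hits", "misses")

    def __init__(self):
        self._store: dict[tuple, float] = {}
        self.hits = 0
        self.misses = 0

    def __len__(self) -> int:
        return len(self._store)

    def clear(self) -> None:
        self._store.clear()
        self.hits = 0
        self.misses = 0

    def get(self, key: tuple) -> float | None:
        value = self._store.get(key)
        if value is None:
            self.misses += 1
        else:
            self.hits += 1
        return value

    def put(self, key: tuple, value: float) -> None:
        self._store[key] = value


def cached_test(cache: ResultCache | None, test: str, c: Contingency,
                direction: str = "over",
                buffer: LogFactorialBuffer | None = None) -> float:
    """Run *test* on *c*, consulting/filling *cache* when one is given."""
    try:
        fn = TESTS[test]
    except KeyError:
        raise ValueError(
            f"unknown test {test!r}; valid tests: {', '.join(TESTS)}"
        ) from None
    if cache is None:
        return fn(c, direction, buffer)
    key = (test, direction, c.k, c.n, c.K, c.N)
    value = cache.get(key)
    if value is None:
        value = fn(c, direction, buffer)
        cache.put(key, value)
    return value
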