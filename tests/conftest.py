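import math

import pytest

from overrep import Background, QuerySet
from overrep.synthetic import SimulationSpec


def bg_spec(n_items, n_terms, seed, **kwargs):
    """Small-background scenario used only for background/null-query draws."""
    kwargs.setdefault("query_size", max(1, n_items // 20))
    kwargs.setdefault("enriched_fraction", 0.0)
    # keep the top-ranked Zipf term's inclusion probability below one
    harmonic = sum(1.0 / r for r in range(1, n_terms))
    kwargs.setdefault("mean_terms_per_item", min(3.0, 0.8 * harmonic))
    return SimulationSpec(n_items=n_items, n_terms=n_terms, seed=seed,
                          **kwargs)


@pytest.fixture
def tiny_background(tmp_path):
    """Three-item background: A carries T1+T2, B carries T1, C nothing."""
    path = tmp_path / "tiny.bg"
    path.write_text("A T1 T2\nB T1\nC\n")
    return path


@pytest.fixture
def small_background():
    """Six items, three terms with carrier counts 3, 2, 1."""
    return Background({
        "A": {"T1", "T2"},
        "B": {"T1"},
        "C": {"T2"},
        "D": {"T1", "T3"},
        "E": set(),
        "F": set(),
    })


@pytest.fixture
def abc_query():
    return QuerySet(name="abc", items=("A", "B", "C"))


def hypergeom_tail_exact(k: int, n: int, K: int, N: int,
                         direction: str) -> float:
    """Brute-force hypergeometric tail via exact integer binomials.

    Independent of the package's log-space path: sums C(K,x)C(N-K,n-x)
    as Python integers and divides once at the end.
    """
    lo, hi = max(0, n + K - N), min(n, K)
    if direction == "over":
        xs = range(k, hi + 1)
    else:
        xs = range(lo, k + 1)
    numerator = sum(math.comb(K, x) * math.comb(N - K, n - x) for x in xs)
    return numerator / math.comb(N, n)


def binom_tail_exact(k: int, n: int, p_num: int, p_den: int,
                     direction: str) -> float:
    """Brute-force binomial tail with rational success probability."""
    from fractions import Fraction
    p = Fraction(p_num, p_den)
    xs = range(k, n + 1) if direction == "over" else range(0, k + 1)
    total = sum(
        math.comb(n, x) * p ** x * (1 - p) ** (n - x) for x in xs
    )
    return float(total)
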