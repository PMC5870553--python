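"""Enrichment orchestration: contingencies, tests, corrections, cutoff,
sorting, filtering, and bulk runs over shared caches.

An enrichment run takes a query set and an annotated background, builds a
2x2 contingency for every *eligible* term (by default, every term carried
by more than one background item), computes the over- and
under-representation tails of the primary test, reports the smaller tail
as the term's direction, adjusts each configured test's p-value column
for multiple testing across the tested terms, and applies an optional
display cutoff.

The default display cutoff is empirical: draw ``n_permutations`` random
item sets of the query's size from the background, record the minimum raw
p-value each produces under the primary test, and average those minima.
Terms whose raw primary p-value exceeds that average are not worth
looking at, because a random set of the same size typically produces
something at least as extreme.  The cutoff is compared against *raw*
p-values since the permutation minima are raw-scale quantities.

Over- and under-representation of the same term count as one hypothesis:
only the reported direction's p-value enters the corrected vector, so the
number of hypotheses equals the number of eligible terms.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

from .background_io import Background, QuerySet, TermInfo
from .corrections import CORRECTIONS, adjust
from .stats_core import (
    Contingency,
    LogFactorialBuffer,
    ResultCache,
    TESTS,
    cached_test,
)

logger = logging.getLogger("overrep")

__all__ = [
    "EnrichmentError",
    "EnrichmentConfig",
    "EnrichmentRecord",
    "EnrichmentReport",
    "Caches",
    "build_contingency",
    "eligible_terms",
    "permutation_cutoff",
    "enrich",
    "bulk_enrich",
    "filter_top_enriched",
]

DEFAULT_TEST_ORDER = ("fisher", "hypergeometric", "binomial")


class EnrichmentError(Exception):
    """An analysis-level failure for one query (e.g. no items matched)."""


@dataclass
class Caches:
    """Shared computation state for a run or a bulk of runs.

    Holds the log-factorial buffer and the p-value result cache.  Sharing
    caches across queries never changes results — it only avoids
    recomputing tails for contingency configurations already seen.
    """

    buffer: LogFactorialBuffer = field(default_factory=LogFactorialBuffer)
    results: ResultCache | None = field(default_factory=ResultCache)


@dataclass(frozen=True)
class EnrichmentConfig:
    """Knobs of an enrichment run.

    Attributes
    ----------
    tests:
        Ordered subset of ``fisher``, ``hypergeometric``, ``binomial``.
        The first listed is the *primary* test: it decides each term's
        direction, drives the permutation cutoff and the default sort.
    correction:
        ``none``, ``bonferroni``, ``bh`` or ``by``.
    cutoff_mode:
        ``permutation`` (empirical average-minimum cutoff), ``fixed``
        (use ``alpha``) or ``none``.
    alpha:
        Fixed cutoff level used when ``cutoff_mode == "fixed"``.
    n_permutations:
        Number of random same-size sets for the permutation cutoff.
    seed:
        Root seed for the permutation streams; ``None`` means
        non-reproducible entropy.
    sort_key:
        Report column to sort by; default is the adjusted (or, without
        correction, the raw) primary-test p-value, ascending.
    min_background_count:
        A term must be carried by at least this many background items to
        be tested (default 2: terms represented more than once).
    namespaces:
        Optional allow-list of term namespaces; requires a term table.
    top_only:
        Keep only the top record (per allowed namespace if a namespace
        filter is active).
    """

    tests: tuple[str, ...] = ("fisher",)
    correction: str = "bh"
    cutoff_mode: str = "permutation"
    alpha: float = 0.05
    n_permutations: int = 100
    seed: int | None = None
    sort_key: str | None = None
    min_background_count: int = 2
    namespaces: tuple[str, ...] | None = None
    top_only: bool = False

    def __post_init__(self):
        if not self.tests:
            raise ValueError("config.tests must name at least one test")
        unknown = [t for t in self.tests if t not in TESTS]
        if unknown:
            raise ValueError(
                f"unknown test(s) {unknown}; valid: {', '.join(TESTS)}"
            )
        if len(set(self.tests)) != len(self.tests):
            raise ValueError("config.tests contains duplicates")
        if self.correction not in ("none", *CORRECTIONS):
            raise ValueError(
                f"unknown correction {self.correction!r}; "
                f"valid: none, {', '.join(CORRECTIONS)}"
            )
        if self.cutoff_mode not in ("permutation", "fixed", "none"):
            raise ValueError(
                f"unknown cutoff mode {self.cutoff_mode!r}; "
                "valid: permutation, fixed, none"
            )
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.min_background_count < 1:
            raise ValueError("min_background_count must be >= 1")

    @property
    def primary(self) -> str:
        return self.tests[0]

    @property
    def effective_sort_key(self) -> str:
        if self.sort_key is not None:
            return self.sort_key
        if self.correction == "none":
            return f"p.{self.primary}"
        return f"padj.{self.primary}"


@dataclass(frozen=True)
class EnrichmentRecord:
    """One term's result: counts, direction, fold change and p-values."""

    term: str
    term_name: str
    namespace: str
    k: int
    n: int
    K: int
    N: int
    direction: str
    fold_enrichment: float
    raw_p: dict[str, float]
    adjusted_p: dict[str, float]


@dataclass(frozen=True)
class EnrichmentReport:
    """Ordered, filtered records for one query, plus run metadata."""

    query_name: str
    records: tuple[EnrichmentRecord, ...]
    cutoff: float | None
    m_tested: int
    dropped_items: int
    config: EnrichmentConfig


def build_contingency(query: QuerySet, background: Background,
                      term: str) -> Contingency:
    """Assemble (k, n, K, N) for one term against one query.

    ``n`` counts only query items present in the background; ``k`` counts
    the matched items that carry the term.
    """
    matched = [item for item in query.items if item in background]
    if not matched:
        raise EnrichmentError(
            f"no query items of {query.name!r} found in background"
        )
    K = background.term_counts.get(term, 0)
    if K < 1:
        raise ValueError(f"term {term!r} has no carriers in the background")
    k = sum(term in background.annotations[item] for item in matched)
    return Contingency(k=k, n=len(matched), K=K, N=background.size)


def eligible_terms(background: Background, min_count: int = 2) -> list[str]:
    """Terms carried by at least *min_count* background items, sorted.

    The default of 2 implements the rule that p-values are computed only
    for categories represented more than once in the background; a
    singleton category can never be informative about a subset.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    return sorted(
        term for term, count in background.term_counts.items()
        if count >= min_count
    )


def _directional_p(cache: ResultCache | None, test: str, c: Contingency,
                   buffer: LogFactorialBuffer) -> tuple[str, float]:
    """Smaller of the over/under tails and its direction (tie -> over)."""
    p_over = cached_test(cache, test, c, "over", buffer)
    p_under = cached_test(cache, test, c, "under", buffer)
    if p_over <= p_under:
        return "over", p_over
    return "under", p_under


def _min_p_for_items(items: list[str], background: Background,
                     terms: list[str], test: str,
                     caches: Caches) -> float:
    """Minimum directional raw p over *terms* for a fixed item set."""
    n = len(items)
    N = background.size
    counts = Counter(
        term for item in items for term in background.annotations[item]
    )
    best = 1.0
    for term in terms:
        c = Contingency(k=counts.get(term, 0), n=n,
                        K=background.term_counts[term], N=N)
        _, p = _directional_p(caches.results, test, c, caches.buffer)
        if p < best:
            best = p
    return best


def permutation_cutoff(background: Background, set_size: int,
                       config: EnrichmentConfig,
                       caches: Caches | None = None,
                       return_minima: bool = False):
    """Average minimum raw p-value over random same-size item sets.

    For each of ``config.n_permutations`` iterations a set of
    ``set_size`` items is drawn uniformly without replacement from the
    background; the primary test runs over all eligible terms and the
    minimum raw (directional) p-value is recorded.  The cutoff is the
    arithmetic mean of those minima.

    Permutation ``i`` uses an independent random stream derived from the
    root seed, so the result does not depend on how iterations might be
    scheduled.  With ``return_minima=True`` the per-permutation minima
    are returned alongside the mean, which lets callers audit the cutoff
    by recomputing the average themselves.
    """
    if not 1 <= set_size <= background.size:
        raise ValueError(
            f"set_size must lie in [1, N={background.size}], got {set_size}"
        )
    caches = caches or Caches()
    terms = eligible_terms(background, config.min_background_count)
    items = background.items
    streams = np.random.SeedSequence(config.seed).spawn(config.n_permutations)
    minima = np.empty(config.n_permutations)
    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        idx = rng.choice(len(items), size=set_size, replace=False)
        sample = [items[j] for j in idx]
        if terms:
            minima[i] = _min_p_for_items(sample, background, terms,
                                         config.primary, caches)
        else:
            minima[i] = 1.0
    cutoff = float(np.mean(minima))
    if return_minima:
        return cutoff, minima
    return cutoff


def _sort_records(records: list[EnrichmentRecord],
                  config: EnrichmentConfig) -> list[EnrichmentRecord]:
    primary = config.primary
    key = config.effective_sort_key

    def column_value(r: EnrichmentRecord):
        if key.startswith("p."):
            return r.raw_p[key[2:]]
        if key.startswith("padj."):
            return r.adjusted_p[key[5:]]
        if key == "fold":
            return -r.fold_enrichment
        if key in ("k", "n", "K", "N"):
            return getattr(r, key)
        if key == "term":
            return r.term
        raise ValueError(f"unknown sort key {key!r}")

    def sort_key(r: EnrichmentRecord):
        # deterministic total order: requested column, then adjusted and
        # raw primary p, descending fold, term ID
        return (
            column_value(r),
            r.adjusted_p[primary],
            r.raw_p[primary],
            -r.fold_enrichment,
            r.term,
        )

    return sorted(records, key=sort_key)


def filter_top_enriched(report: EnrichmentReport) -> EnrichmentReport:
    """Keep only the top-ranked record (per namespace when filtering).

    Assumes the report is already sorted; with an active namespace
    allow-list the head of each allowed namespace is retained, otherwise
    just the overall head.
    """
    if not report.records:
        return report
    namespaces = report.config.namespaces
    if namespaces:
        kept: list[EnrichmentRecord] = []
        seen: set[str] = set()
        for record in report.records:
            if record.namespace in namespaces and record.namespace not in seen:
                kept.append(record)
                seen.add(record.namespace)
        return replace(report, records=tuple(kept))
    return replace(report, records=(report.records[0],))


def enrich(query: QuerySet, background: Background,
           config: EnrichmentConfig | None = None,
           term_info: dict[str, TermInfo] | None = None,
           caches: Caches | None = None) -> EnrichmentReport:
    """Run a full enrichment analysis of one query against a background.

    Returns an `EnrichmentReport` whose records are sorted by the
    configured key and filtered by the display cutoff and any namespace /
    top-only filters.  ``m_tested`` in the report is the number of
    hypotheses entering the correction.
    """
    config = config or EnrichmentConfig()
    caches = caches or Caches()
    term_info = term_info or {}

    matched = [item for item in query.items if item in background]
    dropped = len(query.items) - len(matched)
    if dropped:
        logger.warning(
            "query %r: %d of %d items not in background, dropped",
            query.name, dropped, len(query.items),
        )
    if not matched:
        raise EnrichmentError(
            f"no query items of {query.name!r} found in background"
        )

    terms = eligible_terms(background, config.min_background_count)
    n, N = len(matched), background.size
    counts = Counter(
        term for item in matched for term in background.annotations[item]
    )

    records: list[EnrichmentRecord] = []
    for term in terms:
        c = Contingency(k=counts.get(term, 0), n=n,
                        K=background.term_counts[term], N=N)
        direction, _ = _directional_p(caches.results, config.primary, c,
                                      caches.buffer)
        raw_p = {
            test: cached_test(caches.results, test, c, direction,
                              caches.buffer)
            for test in config.tests
        }
        fold = 0.0 if c.k == 0 else (c.k / c.n) / (c.K / c.N)
        info = term_info.get(term)
        records.append(EnrichmentRecord(
            term=term,
            term_name=info.name if info else "",
            namespace=info.namespace if info else "",
            k=c.k, n=c.n, K=c.K, N=c.N,
            direction=direction,
            fold_enrichment=fold,
            raw_p=raw_p,
            adjusted_p={},
        ))

    m_tested = len(records)
    if m_tested == 0:
        logger.warning(
            "query %r: no eligible terms in background (all counts < %d)",
            query.name, config.min_background_count,
        )
        return EnrichmentReport(
            query_name=query.name, records=(), cutoff=None,
            m_tested=0, dropped_items=dropped, config=config,
        )

    # each test's column is corrected independently across the m terms
    adjusted_columns = {
        test: adjust(config.correction,
                     [r.raw_p[test] for r in records], m_tested)
        for test in config.tests
    }
    records = [
        replace(r, adjusted_p={
            test: float(adjusted_columns[test][i]) for test in config.tests
        })
        for i, r in enumerate(records)
    ]

    if config.cutoff_mode == "permutation":
        cutoff = permutation_cutoff(background, n, config, caches)
    elif config.cutoff_mode == "fixed":
        cutoff = config.alpha
    else:
        cutoff = None

    records = _sort_records(records, config)
    if cutoff is not None:
        records = [r for r in records if r.raw_p[config.primary] <= cutoff]
    if config.namespaces is not None:
        records = [r for r in records if r.namespace in config.namespaces]

    report = EnrichmentReport(
        query_name=query.name, records=tuple(records), cutoff=cutoff,
        m_tested=m_tested, dropped_items=dropped, config=config,
    )
    if config.top_only:
        report = filter_top_enriched(report)
    return report


def bulk_enrich(queries: list[QuerySet], background: Background,
                config: EnrichmentConfig | None = None,
                term_info: dict[str, TermInfo] | None = None,
                caches: Caches | None = None
                ) -> list[EnrichmentReport | EnrichmentError]:
    """Run many queries against one background with shared caches.

    Each list entry is either the query's report or, if that query
    failed, the `EnrichmentError` describing why — one bad query never
    aborts the batch.  Results are element-wise identical to independent
    `enrich` calls with fresh caches.
    """
    if not queries:
        raise ValueError("bulk_enrich: need at least one query set")
    caches = caches or Caches()
    out: list[EnrichmentReport | EnrichmentError] = []
    for query in queries:
        try:
            out.append(enrich(query, background, config, term_info, caches))
        except EnrichmentError as exc:
            logger.error("query %r failed: %s", query.name, exc)
            out.append(exc)
    if caches.results is not None:
        logger.info(
            "bulk run: %d cache hits, %d misses",
            caches.results.hits, caches.results.misses,
        )
    return out
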