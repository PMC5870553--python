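import logging

import numpy as np
import pytest

from overrep import (
    Background,
    Caches,
    EnrichmentConfig,
    EnrichmentError,
    QuerySet,
    build_contingency,
    bulk_enrich,
    eligible_terms,
    enrich,
    filter_top_enriched,
    permutation_cutoff,
)
from overrep.background_io import TermInfo
from overrep.synthetic import (
    SimulationSpec,
    generate_background,
    generate_null_query,
)
from conftest import bg_spec, hypergeom_tail_exact

NO_CUTOFF = EnrichmentConfig(cutoff_mode="none")


class TestBuildContingency:
    def test_hand_counts(self):
        bg = Background({"A": {"T"}, "B": {"T"}, "C": set(), "D": {"T"},
                         "E": set(), "F": set()})
        q = QuerySet(name="q", items=("A", "B", "C"))
        c = build_contingency(q, bg, "T")
        assert (c.k, c.n, c.K, c.N) == (2, 3, 3, 6)

    def test_saturated_query(self, small_background):
        q = QuerySet(name="all", items=small_background.items)
        for term, K in small_background.term_counts.items():
            c = build_contingency(q, small_background, term)
            assert c.k == K and c.n == small_background.size

    def test_term_absent_from_query(self, small_background):
        q = QuerySet(name="q", items=("E", "F"))
        assert build_contingency(q, small_background, "T1").k == 0

    def test_unmatched_query_rejected(self, small_background):
        q = QuerySet(name="q", items=("X", "Y"))
        with pytest.raises(EnrichmentError, match="no query items"):
            build_contingency(q, small_background, "T1")


class TestEligibleTerms:
    def test_default_excludes_singletons(self):
        bg = Background({"A": {"T1", "T2", "T3"}, "B": {"T1", "T2"},
                         "C": {"T1"}})
        assert eligible_terms(bg) == ["T1", "T2"]
        assert eligible_terms(bg, min_count=1) == ["T1", "T2", "T3"]
        assert eligible_terms(bg, min_count=4) == []

    def test_min_count_validation(self, small_background):
        with pytest.raises(ValueError):
            eligible_terms(small_background, 0)


class TestPermutationCutoff:
    def test_degenerate_single_term_background(self):
        bg = Background({f"G{i}": {"T"} for i in range(20)})
        config = EnrichmentConfig(seed=0, n_permutations=10)
        assert permutation_cutoff(bg, 5, config) == 1.0

    def test_seeded_reproducibility(self):
        bg = generate_background(bg_spec(200, 30, 2))
        config = EnrichmentConfig(seed=42, n_permutations=20)
        first = permutation_cutoff(bg, 25, config)
        second = permutation_cutoff(bg, 25, config)
        assert first == second

    def test_single_permutation_equals_its_minimum(self):
        bg = generate_background(bg_spec(100, 10, 3))
        config = EnrichmentConfig(seed=5, n_permutations=1)
        cutoff, minima = permutation_cutoff(bg, 10, config,
                                            return_minima=True)
        assert minima.shape == (1,)
        assert cutoff == minima[0]

    def test_cutoff_is_mean_of_trace(self):
        bg = generate_background(bg_spec(300, 40, 4))
        config = EnrichmentConfig(seed=9, n_permutations=30)
        cutoff, minima = permutation_cutoff(bg, 30, config,
                                            return_minima=True)
        assert cutoff == float(np.mean(minima))

    def test_set_size_out_of_range(self, small_background):
        with pytest.raises(ValueError, match="set_size"):
            permutation_cutoff(small_background, 7, NO_CUTOFF)


class TestEnrich:
    def test_planted_term_ranked_first_with_oracle_p(self):
        spec = SimulationSpec(n_items=1000, n_terms=100,
                              planted_term_frequency=0.05, query_size=50,
                              enriched_fraction=0.8, seed=10)
        bg = generate_background(spec)
        from overrep.synthetic import generate_enriched_query
        query = generate_enriched_query(bg, spec)
        report = enrich(query, bg, NO_CUTOFF)
        top = report.records[0]
        assert top.term == spec.planted_term
        assert (top.k, top.n, top.K, top.N) == (40, 50, 50, 1000)
        oracle = hypergeom_tail_exact(40, 50, 50, 1000, "over")
        assert top.raw_p["fisher"] == pytest.approx(oracle, rel=1e-10)

    def test_fisher_column_independent_of_other_tests(self, small_background,
                                                      abc_query):
        one = enrich(abc_query, small_background,
                     EnrichmentConfig(tests=("fisher",), cutoff_mode="none"))
        two = enrich(abc_query, small_background,
                     EnrichmentConfig(tests=("fisher", "hypergeometric"),
                                      cutoff_mode="none"))
        for a, b in zip(one.records, two.records):
            assert a.term == b.term
            assert a.raw_p["fisher"] == b.raw_p["fisher"]
            assert a.adjusted_p["fisher"] == b.adjusted_p["fisher"]
            assert b.raw_p["hypergeometric"] == b.raw_p["fisher"]

    def test_direction_and_fold_are_consistent(self):
        spec = bg_spec(400, 40, 6)
        bg = generate_background(spec)
        query = generate_null_query(bg, 60, seed=7)
        report = enrich(query, bg, NO_CUTOFF)
        for r in report.records:
            assert r.direction in ("over", "under")
            if r.fold_enrichment > 1.0:
                assert r.direction == "over"
            assert set(r.raw_p) == set(r.adjusted_p)
            for test in r.raw_p:
                assert r.adjusted_p[test] >= r.raw_p[test] - 1e-15

    def test_dropped_items_counted_and_warned(self, small_background, caplog):
        q = QuerySet(name="q", items=("A", "B", "NOT_THERE"))
        with caplog.at_level(logging.WARNING, logger="overrep"):
            report = enrich(q, small_background, NO_CUTOFF)
        assert report.dropped_items == 1
        assert all(r.n == 2 for r in report.records)
        assert any("dropped" in rec.message for rec in caplog.records)

    def test_no_eligible_terms_yields_empty_report(self, caplog):
        bg = Background({"A": {"T1"}, "B": {"T2"}, "C": set()})
        q = QuerySet(name="q", items=("A",))
        with caplog.at_level(logging.WARNING, logger="overrep"):
            report = enrich(q, bg, NO_CUTOFF)
        assert report.records == ()
        assert report.m_tested == 0

    def test_small_universe_matches_brute_force_everywhere(self):
        """Every reported raw p equals exact integer tail enumeration."""
        rng = np.random.default_rng(21)
        for trial in range(20):
            N = int(rng.integers(5, 26))
            n_terms = int(rng.integers(2, 7))
            items = {
                f"G{i}": {f"T{t}" for t in range(n_terms)
                          if rng.random() < 0.4}
                for i in range(N)
            }
            bg = Background(items)
            size = int(rng.integers(1, N + 1))
            query = generate_null_query(bg, size, seed=trial)
            report = enrich(query, bg, NO_CUTOFF)
            for r in report.records:
                oracle = hypergeom_tail_exact(r.k, r.n, r.K, r.N, r.direction)
                assert r.raw_p["fisher"] == pytest.approx(oracle, rel=1e-10)

    def test_fixed_cutoff_filters_records(self):
        spec = bg_spec(500, 50, 8)
        bg = generate_background(spec)
        query = generate_null_query(bg, 40, seed=9)
        report = enrich(query, bg, EnrichmentConfig(cutoff_mode="fixed",
                                                    alpha=0.5))
        assert report.cutoff == 0.5
        assert all(r.raw_p["fisher"] <= 0.5 for r in report.records)

    def test_sorted_by_adjusted_primary_p(self):
        spec = bg_spec(500, 50, 12)
        bg = generate_background(spec)
        query = generate_null_query(bg, 40, seed=13)
        report = enrich(query, bg, NO_CUTOFF)
        adjusted = [r.adjusted_p["fisher"] for r in report.records]
        assert adjusted == sorted(adjusted)


class TestBulk:
    def test_identical_queries_identical_reports(self, small_background,
                                                 abc_query):
        reports = bulk_enrich([abc_query] * 3, small_background, NO_CUTOFF)
        assert reports[0] == reports[1] == reports[2]

    def test_bulk_matches_sequential_fresh_caches(self):
        spec = bg_spec(400, 60, 14)
        bg = generate_background(spec)
        queries = [generate_null_query(bg, 30, seed=s, name=f"q{s}")
                   for s in range(20)]
        config = EnrichmentConfig(cutoff_mode="permutation",
                                  n_permutations=5, seed=77)
        bulk = bulk_enrich(queries, bg, config)
        for query, bulk_report in zip(queries, bulk):
            solo = enrich(query, bg, config, caches=Caches())
            assert solo == bulk_report

    def test_cache_disabled_matches_cache_enabled(self):
        spec = bg_spec(300, 30, 15)
        bg = generate_background(spec)
        queries = [generate_null_query(bg, 25, seed=s, name=f"q{s}")
                   for s in range(5)]
        with_cache = bulk_enrich(queries, bg, NO_CUTOFF, caches=Caches())
        without = bulk_enrich(queries, bg, NO_CUTOFF,
                              caches=Caches(results=None))
        assert with_cache == without

    def test_failing_query_does_not_abort_batch(self, small_background,
                                                abc_query):
        bad = QuerySet(name="bad", items=("NOPE",))
        results = bulk_enrich([abc_query, bad, abc_query],
                              small_background, NO_CUTOFF)
        assert isinstance(results[1], EnrichmentError)
        assert results[0] == results[2]

    def test_empty_batch_rejected(self, small_background):
        with pytest.raises(ValueError):
            bulk_enrich([], small_background)


class TestFilters:
    def _report(self, namespaces=None):
        bg = Background({
            "A": {"T1", "T2"}, "B": {"T1", "T3"}, "C": {"T2", "T3"},
            "D": {"T1"}, "E": set(), "F": set(),
        })
        info = {
            "T1": TermInfo("T1", namespace="F"),
            "T2": TermInfo("T2", namespace="P"),
            "T3": TermInfo("T3", namespace="P"),
        }
        q = QuerySet(name="q", items=("A", "B", "D"))
        config = EnrichmentConfig(cutoff_mode="none", namespaces=namespaces)
        return enrich(q, bg, config, term_info=info)

    def test_head_selection(self):
        report = self._report()
        top = filter_top_enriched(report)
        assert len(top.records) == 1
        assert top.records[0] == report.records[0]

    def test_per_namespace_heads(self):
        report = self._report(namespaces=("F", "P"))
        top = filter_top_enriched(report)
        assert {r.namespace for r in top.records} <= {"F", "P"}
        per_ns = [r.namespace for r in top.records]
        assert len(per_ns) == len(set(per_ns))

    def test_namespace_allow_list_filters_records(self):
        report = self._report(namespaces=("P",))
        assert report.records
        assert all(r.namespace == "P" for r in report.records)

    def test_empty_report_passthrough(self, small_background):
        bg = Background({"A": {"T1"}, "B": set()})
        report = enrich(QuerySet(name="q", items=("A",)), bg, NO_CUTOFF)
        assert filter_top_enriched(report).records == ()


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(tests=()),
        dict(tests=("fisher", "fisher")),
        dict(tests=("chi2",)),
        dict(correction="storey"),
        dict(cutoff_mode="bootstrap"),
        dict(alpha=0.0),
        dict(n_permutations=0),
        dict(min_background_count=0),
    ])
    def test_bad_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EnrichmentConfig(**kwargs)

    def test_primary_is_first_listed(self):
        config = EnrichmentConfig(tests=("binomial", "fisher"),
                                  cutoff_mode="none")
        assert config.primary == "binomial"
        assert config.effective_sort_key == "padj.binomial"
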