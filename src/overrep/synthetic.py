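"""Seeded generators for synthetic annotation backgrounds and query sets.

Real annotation corpora (e.g. GO on a proteome) have heavily skewed term
usage: a few broad terms annotate large fractions of the universe while
most terms are rare.  The generator emulates that with Zipf-ranked term
inclusion probabilities (exponent ``s``, ``s=0`` giving the uniform case
useful for analytic checks).  One designated *planted* term annotates an
exact, known number of items, so query sets built around its carriers
have a contingency table that is known in advance — the basis for
parameter-recovery tests and demos.

Term-item assignments are independent across terms; there is no
ontology DAG and no term co-occurrence structure.  That is sufficient
for exercising a tool that tests terms independently, but it means
passing tests here say nothing about correlated-annotation behaviour on
real ontologies.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass

import numpy as np

from .background_io import Background, QuerySet

__all__ = [
    "SimulationSpec",
    "generate_background",
    "generate_null_query",
    "generate_enriched_query",
    "planted_truth",
]

#: Identifier of the planted term inside generated backgrounds.
PLANTED_TERM = "T0000"


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of a synthetic enrichment scenario.

    Attributes
    ----------
    n_items:
        Background size N (>= 10).
    n_terms:
        Vocabulary size, including the planted term (>= 2).
    zipf_exponent:
        Skew ``s`` of the rank-frequency law for non-planted terms;
        0 means uniform.
    mean_terms_per_item:
        Expected number of annotations per item, planted term included.
    planted_term_frequency:
        Fraction of items carrying the planted term; its carrier count
        ``K = round(frequency * n_items)`` is enforced exactly.
    query_size:
        Size of generated query sets.
    enriched_fraction:
        Fraction of an enriched query drawn from planted-term carriers.
    seed:
        Root seed; all generated artefacts are deterministic under it.
    """

    n_items: int = 1000
    n_terms: int = 100
    zipf_exponent: float = 1.0
    mean_terms_per_item: float = 3.0
    planted_term_frequency: float = 0.05
    query_size: int = 50
    enriched_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_items < 10:
            raise ValueError("n_items must be >= 10")
        if self.n_terms < 2:
            raise ValueError("n_terms must be >= 2")
        if self.zipf_exponent < 0:
            raise ValueError("zipf_exponent must be >= 0")
        if self.mean_terms_per_item <= 0:
            raise ValueError("mean_terms_per_item must be > 0")
        if not 0.0 < self.planted_term_frequency < 1.0:
            raise ValueError("planted_term_frequency must lie in (0, 1)")
        if not 1 <= self.query_size <= self.n_items:
            raise ValueError("query_size must lie in [1, n_items]")
        if not 0.0 <= self.enriched_fraction <= 1.0:
            raise ValueError("enriched_fraction must lie in [0, 1]")
        if self.planted_count < math.ceil(
                self.enriched_fraction * self.query_size):
            raise ValueError(
                "planted-term carriers fewer than the enriched part of the "
                "query; raise planted_term_frequency or shrink the query"
            )

    @property
    def planted_term(self) -> str:
        return PLANTED_TERM

    @property
    def planted_count(self) -> int:
        """Exact carrier count K of the planted term."""
        return round(self.planted_term_frequency * self.n_items)


def _term_ids(n_terms: int) -> list[str]:
    width = max(4, len(str(n_terms)))
    return [f"T{i:0{width}d}" for i in range(n_terms)]


def _inclusion_probabilities(spec: SimulationSpec) -> np.ndarray:
    """Per-term Bernoulli inclusion probabilities for non-planted terms.

    Scaled so the expected number of annotations per item, including the
    planted term's forced frequency, equals ``mean_terms_per_item``.
    """
    budget = spec.mean_terms_per_item - spec.planted_term_frequency
    if budget <= 0:
        raise ValueError(
            "mean_terms_per_item leaves no annotation budget beyond the "
            "planted term"
        )
    ranks = np.arange(1, spec.n_terms, dtype=np.float64)
    weights = ranks ** -spec.zipf_exponent
    probs = budget * weights / weights.sum()
    if np.any(probs > 1.0):
        raise ValueError(
            "infeasible spec: a term's inclusion probability exceeds 1; "
            "lower mean_terms_per_item or the Zipf exponent, or add terms"
        )
    return probs


def _rng(spec: SimulationSpec, stream: int) -> np.random.Generator:
    # distinct derived streams so background and query draws never overlap
    return np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(stream,))
    )


def generate_background(spec: SimulationSpec) -> Background:
    """Sample a background: forced planted-term count, Zipf-skewed rest."""
    probs = _inclusion_probabilities(spec)
    rng = _rng(spec, stream=0)
    items = [f"G{i:06d}" for i in range(spec.n_items)]
    terms = _term_ids(spec.n_terms)

    annotations: dict[str, set[str]] = {item: set() for item in items}
    carrier_idx = rng.choice(spec.n_items, size=spec.planted_count,
                             replace=False)
    for j in carrier_idx:
        annotations[items[j]].add(spec.planted_term)
    for term, p in zip(terms[1:], probs):
        mask = rng.random(spec.n_items) < p
        for j in np.flatnonzero(mask):
            annotations[items[j]].add(term)
    return Background(annotations)


def generate_null_query(background: Background, size: int,
                        seed: int | None = None,
                        name: str = "null") -> QuerySet:
    """Uniform sample of *size* items without replacement."""
    if not 1 <= size <= background.size:
        raise ValueError(
            f"query size must lie in [1, N={background.size}], got {size}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(background.size, size=size, replace=False)
    return QuerySet(name=name,
                    items=tuple(background.items[j] for j in sorted(idx)))


def generate_enriched_query(background: Background,
                            spec: SimulationSpec,
                            name: str = "enriched") -> QuerySet:
    """Query with a known planted-term count.

    Exactly ``round(enriched_fraction * query_size)`` items come from the
    planted term's carriers, the remainder from non-carriers, both drawn
    without replacement — so the planted contingency (k, n, K, N) is
    fully determined by the spec.
    """
    carriers = background.carriers(spec.planted_term)
    others = [i for i in background.items
              if spec.planted_term not in background.annotations[i]]
    n_enriched = round(spec.enriched_fraction * spec.query_size)
    n_other = spec.query_size - n_enriched
    if n_enriched > len(carriers):
        raise ValueError(
            f"need {n_enriched} planted-term carriers, background has "
            f"{len(carriers)}"
        )
    if n_other > len(others):
        raise ValueError(
            f"need {n_other} non-carriers, background has {len(others)}"
        )
    rng = _rng(spec, stream=1)
    picked = list(rng.choice(carriers, size=n_enriched, replace=False))
    picked += list(rng.choice(others, size=n_other, replace=False))
    return QuerySet(name=name, items=tuple(picked))


def planted_truth(spec: SimulationSpec) -> dict:
    """Ground truth of a scenario, suitable for a JSON sidecar."""
    return {
        "spec": asdict(spec),
        "planted_term": spec.planted_term,
        "K": spec.planted_count,
        "expected_k": round(spec.enriched_fraction * spec.query_size),
        "n": spec.query_size,
        "N": spec.n_items,
    }


def write_truth_sidecar(spec: SimulationSpec,
                        path: str | os.PathLike) -> None:
    """Write the scenario's ground truth as JSON next to generated files."""
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(planted_truth(spec), handle, indent=2)
        handle.write("\n")
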