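# Methods

## Model

Over-representation analysis conditions on the margins of a 2×2 table.
A query of `n` items (after matching to the background) contains `k`
carriers of a term that annotates `K` of the `N` background items.
Under the null hypothesis that the query is an exchangeable draw from
the background, `k` follows the hypergeometric distribution with
parameters `(N, K, n)`; the one-sided Fisher exact test reports the
tail `P(X ≥ k)` (over-representation) or `P(X ≤ k)`
(under-representation).  The binomial test replaces sampling without
replacement by `n` independent trials at rate `K/N`; it converges to
the hypergeometric tail as `N` grows with `K/N` fixed and is kept for
comparability with tools that report it.

The "hypergeometric test" exposed by the interface is definitionally
the same number as the one-sided Fisher test on a 2×2 table.  Both
names are kept because the field's tools conventionally list them as
separate tests; the implementation delegates one to the other and a
regression test asserts bit-identity, so the duplication can never
drift.

Each term is a separate, independent hypothesis: there is no ontology
graph, no up-propagation of annotations to ancestor terms and no
elimination/weighting scheme.  The reported direction of a term is
whichever tail of the primary test is smaller (ties report "over");
over- and under-representation of one term count as a single hypothesis
so the family size is the number of eligible terms, not twice that.

## Numerics

Tails are evaluated in log space.  A shared append-only buffer stores
`ln(i!)` with `values[i] = values[i-1] + ln(i)` and grows by amortised
doubling; log-binomial coefficients come from three lookups.  A tail is
summed from the extreme end of the support inward (smallest terms
first): the log-pmf values are shifted by their maximum, exponentiated
once each, accumulated with compensated summation, and re-exponentiated.
Results are clamped into `(0, 1]` — a table so extreme that the tail
underflows double precision reports the smallest positive double rather
than an exact zero, since a zero p-value is always wrong.

The result cache maps `(test, direction, k, n, K, N)` to the computed
p-value.  The key is deliberately finer than the contingency alone so a
hit can never return a value computed under different semantics.  The
cache is a pure accelerator; a dedicated suite asserts that cache
on/off, cache clearing, and bulk-versus-sequential execution leave
reports byte-identical.

## Eligibility, correction, cutoff

Terms carried by fewer than two background items are not tested by
default (`min_background_count = 2`): a singleton category cannot be
informative about a subset and would only inflate the hypothesis count.
The correction family size `m` is the number of terms actually tested.

Bonferroni, Benjamini–Hochberg and Benjamini–Yekutieli are implemented
directly (step-up with cumulative minima, BY with the harmonic factor
`c(m)`), and verified against statsmodels to relative 1e-12 on random
vectors up to `m = 10⁴`.  BY ≥ BH and Bonferroni ≥ BH hold elementwise
by construction.  Bonferroni and BY are *not* mutually ordered: for
`p = [0.25, 1.0]`, Bonferroni adjusts the first entry to 0.5 while BY
gives 0.75, because BY's step-up minimum at rank 1 carries the factor
`c(m)` but not the full rank division.  The tests assert only the true
dominance relations.

The permutation cutoff draws `n_permutations` (default 100) item sets
of the query's size uniformly without replacement from the background,
runs the primary test over all eligible terms, records each set's
minimum raw directional p-value, and averages the minima.  Records are
filtered on the primary test's **raw** p-value (inclusive, ≤), since
the permutation minima are raw-scale quantities.  Permutation `i` draws
from a child stream of `SeedSequence(seed)` spawned at index `i`, so
the cutoff is independent of any execution-order concern and
bit-reproducible under a fixed seed.  The cutoff function can return
its per-permutation minima so callers can audit the average.

Where several tests are configured, the first listed is the *primary*
test: it decides direction, drives the cutoff and the default sort.
Each test's p-value column is corrected independently; pooling columns
would count the same hypothesis multiple times.

## Sorting and ties

Reports sort ascending by the adjusted primary p-value (raw, when no
correction is applied) with a deterministic tie-break chain: adjusted
primary p, raw primary p, descending fold enrichment, term identifier.
Fold enrichment is `(k/n)/(K/N)`; `k = 0` reports fold 0, and
under-represented terms show folds below 1 rather than reciprocals so
the scale stays monotone.

## Input handling

Backgrounds are plain text: first whitespace-separated token on a line
is the item, the remaining tokens are its terms; `#` starts a comment.
Repeated item lines union their term sets, so concatenating background
files equals merging them.  Identifier matching is case-sensitive with
no normalisation — silent case-folding corrupts mixed-source
identifiers, so the package refuses to guess.  Query items absent from
the background are dropped with a warning and a per-report count;
`n` counts only matched items, since the test is conditioned on the
background universe.  This exclusion rule is a documented convention;
tools that keep unmatched items in `n` will report slightly different
p-values on unclean inputs.

The GAF 2.x reader is minimal by design: DB object ID → item, GO ID →
term, aspect code → namespace, `NOT`-qualified rows excluded, short
rows skipped with a warning.  There is no OBO parsing and no online
fetching.

## Synthetic data

The generator emulates the shape of real annotation corpora that
matters to an enrichment engine: a background of `n_items` items, a
vocabulary whose non-planted terms have Zipf-ranked inclusion
probabilities (exponent `s`, default 1, matching the few-common /
many-rare skew of real term usage; `s = 0` gives the uniform case for
analytic checks), scaled so the expected annotations per item equal
`mean_terms_per_item`, and one planted term whose carrier count
`K = round(frequency · n_items)` is enforced exactly.  Enriched queries
draw a fixed fraction of their items from the planted term's carriers,
making the planted contingency known in advance.

Defaults describe the canonical recovery scenario used throughout the
tests: `N = 1000`, 100 terms, planted frequency 0.05 (so `K = 50`),
query size 50, enriched fraction 0.8 (so `k = 40`), around three
annotations per item.

Term–item assignments are independent across terms: there is no
ontology DAG, no term co-occurrence and no annotation bias by item
"size".  Passing tests on this generator therefore demonstrate the
engine's arithmetic, calibration and plumbing — not robustness to the
correlated annotation structure of real ontologies, which an engine
that tests terms independently does not model in any case.

## Problem sizes and verification

The automated checks run at desk scale, chosen to exercise every code
path with tight oracles: exhaustive tail verification on all ~23 000
valid tables with `N ≤ 25` (relative 1e-10 against integer-arithmetic
sums) plus 1000 random tables up to `N = 5000` against scipy;
correction agreement with statsmodels on 1000 random vectors; type-I
calibration over 200 null queries (the measured rejection rate at
α = 0.05 is ~0.03 — exact tests on discrete support are conservative,
so below-nominal rates are expected); planted recovery across enriched
fractions 0.2–0.8; and a bulk throughput run of 100 query sets of 100
items against a 20 000-item × 5 000-term background, which completes in
seconds thanks to the result cache (wall-clock is reported, not
asserted, as it is hardware-dependent).

## Known limitations

- No ontology awareness: parent terms are tested only as annotated,
  and correlated terms are corrected as if independent (BY is provided
  for exactly this dependence concern).
- The binomial test is an approximation; on small backgrounds it can
  disagree noticeably with the exact tail and is not the default.
- The permutation cutoff is a display heuristic, not an error-rate
  guarantee; it controls what is shown, not what is significant.
- Backgrounds are held in memory as per-item term sets; this is
  comfortable at proteome scale but not designed for corpora orders of
  magnitude larger.
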