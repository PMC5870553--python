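# overrep

Fast, scriptable functional over-representation analysis for gene and
protein sets.

Given a list of items produced by some analysis (a cluster of genes, a
set of proteins sharing a property) and an annotated background universe
(a genome, a proteome), `overrep` asks, for every annotation term: does
this term appear in the list more (or less) often than a random list of
the same size would show?  It answers with exact one-sided tests,
corrects for the thousands of hypotheses involved, and — unlike a fixed
significance threshold — derives its display cutoff empirically from the
background itself.

It is a library first and a command-line tool second, aimed at
bioinformatics workflows where enrichment runs in a shell pipeline over
many input sets, not through a web form.

## The statistics

For a term annotating `K` of the `N` background items, observed `k`
times in a query of `n` matched items, the one-sided Fisher exact
p-value is the hypergeometric tail

```
P(X ≥ k) = Σ_{x=k}^{min(n,K)}  C(K,x) · C(N−K, n−x) / C(N,n)
```

for over-representation, and `P(X ≤ k)` for under-representation; each
term is reported in the direction with the smaller tail.  A binomial
approximation (`n` trials at success rate `K/N`) is also available, and
"hypergeometric" is exposed as a test name alongside "fisher" for parity
with other enrichment tools (on a 2×2 table they are the same number;
the package computes them identically and says so).

All tails are computed in log space through a dynamically grown
log-factorial buffer, summed from the extreme end of the support inward,
so proteome-scale tables neither overflow nor lose tiny p-values.  A
result cache keyed by `(test, direction, k, n, K, N)` makes bulk runs
over one background fast: random query sets keep hitting the same
contingency configurations.

Raw p-value columns are adjusted by Bonferroni, Benjamini–Hochberg or
Benjamini–Yekutieli across the terms actually tested (by default, terms
carried by at least two background items).  The default display cutoff
is a permutation quantity: draw 100 random same-size sets from the
background, record each set's minimum raw p-value, and average them —
terms whose raw p exceeds that average are no better than noise of the
same shape.

## Worked example

Generate a synthetic scenario — 1000 items, 100 terms with Zipf-skewed
usage, a planted term carried by 50 items, and a 50-item query of which
80% are carriers of the planted term — then analyse it:

```
$ overrep simulate --n-items 1000 --n-terms 100 --query-size 50 \
      --enriched-fraction 0.8 --seed 7 -o demo
$ overrep enrich demo.bg demo.query --seed 7 --format pretty
term   name  namespace  k   n   K   N     fold   direction  p.fisher  padj.fisher
-----  ----  ---------  --  --  --  ----  -----  ---------  --------  -----------
T0000                   40  50  50  1000  16     over       1.71e-52  1.71e-50
T0012                   8   50  46  1000  3.478  over       1.34e-03  6.69e-02
T0049                   3   50  12  1000  5      over       1.88e-02  6.27e-01
```

The planted term `T0000` is recovered at rank 1: 40 of the 50 query
items carry it versus 50 of 1000 in the background, a 16-fold
enrichment with a Fisher tail of 1.7·10⁻⁵², still 1.7·10⁻⁵⁰ after BH
adjustment across the 100 tested terms.  The two other displayed terms
survive the permutation cutoff (the average minimum p of 100 random
50-item sets) but not, after correction, a 5% FDR.  Output is TSV by
default for downstream parsing; `--format pretty` aligns columns and
can colour records below the cutoff on a terminal.

Bulk mode shares the parsed background and the caches across many query
files (`overrep enrich bg.tsv set*.txt`); `overrep background
merge|from-gaf|stats` covers background housekeeping, including a
minimal GAF 2.x reader for Gene Ontology annotation.

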