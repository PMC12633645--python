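# Methods

## Model

A temporal gene co-expression network is stored in snapshot-based
representation: an ordered list of static undirected graphs, one per time
point, over a single immutable node set. Time points are the six decade
donor age groups used by GTEx — 20-29, 30-39, 40-49, 50-59, 60-69, 70-79
years — normalized internally to hyphenated ASCII labels (bracketed or
en-dash forms such as `[20–29]` are accepted on input; exporters always
emit the ASCII form, for file-name and CSV safety).

For genes G = {g₁ … g_k} the candidate set is all unordered pairs
P = {{gᵢ, gⱼ} : i < j}, realized as lexicographic order on the canonical
gene identifiers so that pair orientation is deterministic and independent
of input order. Within each age group, samples from all selected tissues
are pooled into one stratum, and each pair is tested on its sample-aligned
stratum vectors with Pearson's correlation coefficient; the p-value is
two-sided, from the exact t-distribution with n − 2 degrees of freedom
(t = r·√((n−2)/(1−r²))), not a normal approximation — small per-stratum
sample sizes are the expected regime. The snapshot retains an edge exactly
when the p-value is defined and strictly below α; a pair sitting exactly at
α is excluded. The default α is 0.05 and is user-configurable.

Assumptions worth stating explicitly:

* **Pooling across tissues.** Edge sets are defined per age group only, so
  samples of all selected tissues within an age group are pooled into one
  correlation. Per-tissue correlation with subsequent combination is a
  defensible alternative; pooling is isolated behind `stratify` so that
  alternative could be added without touching the builder.
* **Two-sided test.** Negative co-expression counts as a contact. A
  `positive_only` switch restricts edges to r > 0 for users who define
  co-expression as positive correlation only.
* **Raw p-values by default.** Edges are filtered on uncorrected per-pair
  p-values. With 28 pairs × 6 age groups this admits roughly
  28·6·α ≈ 8 false edges per run at α = 0.05 — visible as the ~0.3
  precision in the acceptance report's planted-recovery experiment, which
  is a property of the method, not a defect of the implementation. An
  optional Benjamini–Hochberg mode (`bh=True`, applied within each
  snapshot) is available, off by default.
* **Linear association only.** Pearson's r captures linear relationships;
  mutual information, partial/distance correlation and time-lagged methods
  are out of scope.

## Degenerate inputs and numerical choices

* Strata with n < 3 are built but flagged *undersized*; every pair result
  in them is undefined (reason code `undersized`) and no edge is emitted.
* A constant expression vector makes r undefined; the pair is flagged
  (reason code `constant`), never an exception mid-run.
* r is clamped to [−1, 1] to absorb floating-point fuzz from the library
  routine.
* Parallelism is per time point (the natural independent unit); results
  are assembled in age-group order, not completion order, so output is
  bit-identical for any worker count.
* Edge-list p-values are printed with six decimals and values below 1e−6
  are annotated with the literal string `0.0`; this floor is applied at
  formatting time only — the in-memory and JSON-sidecar values keep full
  precision. Re-importing an edge list therefore reproduces edge sets
  exactly and p-values to ±5e−7. Network assembly re-validates the
  "retained edge has p < α" invariant with a +1e−6 tolerance precisely so
  that a 6-decimal rounding at the threshold cannot make a legitimately
  exported file unreadable.

## Identifier harmonization

Aliases resolve against a TSV reference table (columns `symbol`,
`canonical_id`, optional `gene_type`, `description`, pipe-separated
`aliases`). Matching tries exact canonical ID, then version-tolerant ID
(an unversioned `ENSG…` query matches the table's versioned entry), then
case-insensitive symbol, then case-insensitive alias. Duplicate aliases
collapse to one record preserving first-occurrence order; an alias matching
several rows raises rather than guessing; unresolved aliases fail the run
in strict mode (default) or warn in lenient mode — silently dropping a gene
would silently change the pair set. The bundled
`data/reference_genes.tsv` is a hand-curated ten-row subset covering the
case-study panel plus two common aging-related genes; it is a fixture for
examples and tests, not an annotation resource. When the expression matrix
keys rows by unversioned IDs or by symbols (common in hand-made fixtures),
the builder matches resolved records to dataset rows under any of the three
identifier forms.

## Synthetic data generator

The generator emulates the *shape* of age-stratified multi-tissue bulk
expression: a genes × samples matrix whose samples carry tissue labels
(assigned round-robin from the stratum's tissue list) and canonical age
groups. Baseline values are i.i.d. normal with mean `base_mean` = 10 and
standard deviation `noise_sd` = 2, clipped at zero to stay on a
non-negative expression-like scale; at the default mean/sd the clipping
probability is ≈3e-7 per value, so planted correlations are not visibly
attenuated (the clipped fraction is logged). A planted contact replaces
one pair's rows in one stratum with a bivariate normal draw at target
correlation ρ, shifted and scaled the same way, giving an analytic ground
truth for Pearson's r on the generated scale. A gene may appear in at most
one planted contact per age group, so targets never interfere. Everything
is drawn from one `numpy` Generator seeded by the design, and file output
is byte-identical across runs of the same design.

What the generator deliberately does **not** model: negative-binomial
count noise, donor covariates, tissue-specific baselines, or uneven
sample availability across strata. Tests passing on this generator
therefore demonstrate the statistical and structural correctness of the
construction method (calibration, power, invariants), not robustness to
real RNA-seq noise or confounding.

Default study conditions used by the acceptance checks: the case-study
shape (8 genes, 13 brain tissue labels, six age groups) with n = 50
samples per stratum, 200 replicates for calibration/power, planted
ρ = 0.9. At those settings the t-test p-value for a planted pair is
≈1e-18, so recall ≥ 0.99 is the expected behaviour, and under the null
the retained-edge fraction is binomial around α. Structural property
checks run over 100 randomized small designs (3–6 genes, 2–4 strata,
8–24 samples per stratum), sizes chosen to keep the default suite fast
while still exercising every code path; worker-count invariance is
byte-compared on a subset because process pool startup, not the check,
dominates its cost.

## Interfaces

Expression input is GCT 1.2 (version line, dimensions line, `Name` /
`Description` columns) or a plain TSV with the gene ID in the first
column; readers tolerate CRLF and trailing blank lines. Sample attributes
are a TSV with `sample_id`, `tissue`, `age_group`. Samples whose age label
is not one of the six canonical bins are dropped with a logged count —
they carry no usable time point — and every expression column must have an
annotation row. Exports: per-snapshot CSV edge lists with the exact header
`source,target,pvalue` (the column set Cytoscape's table import expects),
per-snapshot adjacency lists in the `node: neighbor1 neighbor2` dialect
(every node listed, isolated ones included, symmetric by construction),
and a JSON sidecar carrying nodes, α, age-group labels and full-precision
edge arrays for programmatic round-trip. The adjacency-list textual
dialect is this package's choice; no interchange standard pins it down.

The HTTP facade (`tgcn --serve`, `POST /tgcn` with
`{"genes": [...], "tissues": null, "threshold": 0.05}`) is a thin
stateless layer over the same engine, implemented on the standard
library's `http.server`; request validation mirrors the CLI invariants
(nonempty gene list, 0 < threshold < 1) and returns 422/500-style JSON
errors. The CLI and the facade produce identical sidecar JSON for
identical parameters, which the test suite asserts.

## Known limitations

* Pooling tissues within an age group conflates tissue heterogeneity with
  co-expression; with strongly tissue-specific genes this can create or
  mask edges.
* No resampling or reweighting compensates for unevenly sized strata;
  undersized strata are only flagged and excluded from edge formation.
* The snapshot model treats age groups as ordered but exchangeable in the
  statistics: no information is shared across time points and no temporal
  smoothing or lag structure is inferred.
* Raw-p filtering trades precision for fidelity to the simple
  threshold-per-pair definition; use the BH mode when precision matters.
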