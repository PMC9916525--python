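# Methods

## The design being modelled

The pipeline targets a reprogramming study with one fibroblast baseline
sample and several clonal iPSC lines, each sequenced once.  Nothing in
the statistics assumes more than one baseline (replicate baselines, if
given, are pooled by summation in the tests and averaged in the count
filter), and every stage is deterministic given its inputs.

## Differential expression without replicates

With unreplicated samples a dispersion cannot be estimated, so the
per-gene statistic is the exact conditional binomial test for the ratio
of two Poisson rates.  Conditional on the total count *t = a + b* of a
gene in a (line, baseline) pair, *a* ~ Binomial(*t*, π) under the null
of equal relative abundance, with π the line's share of the summed
library sizes.  The two-sided p-value is the minimum-likelihood tail:
the sum of P(*x*) over all outcomes with P(*x*) ≤ P(*a*).  Outcomes
tied with the observed probability are included up to a relative
tolerance of 1e-12; when every outcome qualifies (the observed value is
the conditional mode) the p-value is exactly 1.  The implementation is
checked against full enumeration in exact rational arithmetic for all
totals ≤ 25 at library ratios 1, 2 and 10.

Assumptions and their price:

- *Poisson-level variation within a sample.*  The conditional binomial
  null is exact for Poisson counts.  Under over-dispersed
  (negative-binomial) counts the test is anti-conservative: with counts
  near 500 and dispersion 0.02 the variance inflation is roughly
  1 + φμ ≈ 11, so raw p-values under the null are far smaller than
  uniform.  This is intrinsic to any test on an unreplicated design,
  not an implementation artifact.  Consequently the p-value calibration
  test runs in the Poisson limit (dispersion 1e-4), where the test is
  exact and mildly conservative at small totals, while calibration
  under realistic dispersion is asserted on the pipeline's actual
  rejection rule: a *direction* call additionally requires
  |log₂FC| ≥ 1, which screens out the small fold-change fluctuations
  that inflate raw p-values.  Under the default generator the observed
  null direction-call rate is ≈ 0.5%, well below α = 0.05.
- *Fold change*: CPM ratio with pseudocount 1 added to raw counts
  before library scaling.  The pseudocount stabilises zeros and biases
  small-count ratios toward 0 by at most ~0.23 log₂ units at a baseline
  mean of 5 (visible in the generator-calibration test, which allows
  ±0.5 around the planted +3).
- *Significance measure*: Benjamini–Hochberg within each line (each
  line-versus-baseline contrast is its own hypothesis family), default
  `significance_on="q"` at α = 0.05; raw p is selectable because both
  conventions are common in this literature.

## Enrichment and term selection

Over-representation is the upper hypergeometric tail
P(X ≥ k | N, K, n), computed per term against the count-matrix
universe, with BH within each of the six annotation levels (levels are
distinct hypothesis families).  Terms disjoint from the universe are
skipped with a warning rather than scored.  Selection for the group-1
screen takes the 20 smallest-p terms per GO level (ties: larger
overlap, then term id) and all KEGG terms with q < 0.05, plus a
configurable always-include list of stemness pathways
(`DEFAULT_STEMNESS_PATHWAYS`: apoptosis, oxidative phosphorylation,
pluripotency regulation, PI3K, MAPK, Wnt, JAK-STAT, TGF-β); forced
terms are flagged `forced` in the output.

## Screens

All screens share `CountFilterSpec`: baseline count ≤ `max_baseline`
(50) and line counts ≥ `min_line` (20).  How the line condition pools
across the 7 lines is genuinely open; the default is the mean line
count (robust to a single dropout line and closest to a per-group
reading of the thresholds), with `all_lines`, `any_line` and
`at_least_k` selectable.  "Up-regulated" defaults to *up in ≥ 1 line*
(`min_up_lines` configurable).  Group-2 subdataset selection requires a
term to hold ≥ 3 detected inducible genes at GO levels and ≥ 2 at KEGG
levels (levels differ in term granularity); both thresholds are
configurable because only the outcome, not the rule, is conventional.
Group 3 ranks by raw counts, not CPM, matching the "copy number"
reading; ties break on the uppercased gene id everywhere, so all
outputs are reproducible byte for byte.

A property worth knowing: the group-3 *top-k union* is not monotone in
the count thresholds.  Tightening `min_line` removes high-count
competitors and can promote a previously rank->k gene into a line's top
30, growing the union.  Monotonicity holds — and is tested — at the
level of the qualifying pools and the intersection-based screens
(groups 1 and 2); the top-k union is instead verified against an
independent per-line sort oracle.

## Network core

Screened genes (groups 1 ∪ 2) are induced into the background
interaction graph (STRING-style edge table, `combined_score` 0–1000,
default inclusive threshold 400 = medium confidence).  Connected
components with ≥ 6 proteins are retained; genes with degree ≥ 4
("more than three connections") *within their retained component* are
the core.  Degree is counted after induction, not in the background
graph: the deliberate reading is that hubs of the candidate
sub-network, not global hubs, mark the co-regulated core.  Both
thresholds are parameters.  The final table is the union of core and
supplementary genes; its size always satisfies the inclusion–exclusion
identity |core| + |supplementary| − |core ∩ supplementary|.

## The synthetic-study generator

`synthdata.SimConfig` defaults are the study conditions the tests run
under:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | gene universe (desk-scale stand-in for a full transcriptome) |
| `n_lines` | 7 | reprogrammed lines; 1 baseline (`n_baseline_replicates`) |
| `lib_size_baseline/line` | 1e6 | expected column totals (counts) |
| `dispersion` | 0.02 | NB dispersion φ, var = μ + φμ² (clonal lines, low biological noise) |
| `base_mean_log_mean/sd` | 0 / 1 | log-normal gene abundance profile |
| `n_planted_up/down` | 100 / 100 | planted pluripotency / fibroblast blocks |
| `up_log2fc`, `down_log2fc` | +3 / −3 | planted effects |
| `planted_up_base_range` | (5, 30) | expected *baseline* counts of the up block |
| `n_terms_per_level`, `term_size_range` | 20, (10, 50) | catalog shape |
| `n_enriched_terms_per_level`, `enriched_fraction` | 3, 0.8 | terms over-drawing from the up block |
| `ppi_core_size`, `ppi_core_edge_prob` | 6, 1.0 | planted complete interaction core |
| `ppi_background_edge_prob` | 0.003 | Erdős–Rényi background edges |
| `n_inducible` | 25 | literature-style inducible list (subset of the up block) |

Design choices that matter:

- **The up block is planted on genes weakly expressed in the
  baseline** (expected baseline counts uniform on 5–30).  A
  pluripotency programme is off in fibroblasts, and the downstream
  abundance filter (baseline ≤ 50) presumes exactly that; planting the
  block at typical abundance would make the generator's truth
  unreachable by the screen it is meant to exercise.  A side benefit is
  that the planted mass is small, so the compositional shift that
  strong planted effects impose on CPM normalisation is negligible.
- Expected counts are library size × relative abundance after fold
  changes, renormalised per sample, so expected column totals equal the
  configured library sizes exactly.
- Confidence scores are uniform on [400, 1000], so default score
  thresholds keep every generated edge.
- One master seed; sub-generators use fixed offsets (+0 counts,
  +1 annotations, +2 network, +3 inducible list), recorded in the run
  manifest.  All three generators are pure functions of (config, seed).

What the generator does **not** emulate — and hence what passing tests
do not show about real data: GC/length biases, transcript-level
structure, correlated gene programmes beyond the planted blocks,
annotation incompleteness and redundancy between levels, false edges
correlated with abundance in interaction databases, and batch effects.
Recovery rates on synthetic data are upper bounds, not forecasts.

## Cross-species comparison

DE gene lists are translated through a user-supplied ortholog table
(`source_symbol, target_species, target_symbol`; duplicate
(source, species) pairs rejected, many-to-one collapses flagged), with
uppercase symbol identity as a logged approximate fallback.
`venn_counts` tallies every membership-pattern region for 2–4 named
sets; region counts always sum to the union size.  Reproducing any
particular published overlap requires the corresponding external
datasets and is out of scope.

## Numerical and degenerate-input conventions

- Gene identity is the uppercased symbol everywhere; all joins are
  case-insensitive.
- p-values are clipped to (0, 1]; *t* = 0 gives p = 1; empty queries
  give p = 1 for every term.
- Empty term selections or undetected inducible lists yield empty
  screens with a warning, not errors; unknown genes passed to the count
  filter are errors naming the gene.
- Exit codes: 0 success, 1 user error, 2 internal error; logs go to
  stderr, data only to files.

## Problem sizes used by the test suite

The shared test study is the default configuration (2000 genes × 8
samples) plus a 300-gene small study for I/O and screen tests; the
null-calibration simulations use 1500 genes × 7 lines at library size
3×10⁵ (10 500 gene-line pairs).  These sizes were chosen as the
smallest at which the planted-recovery and calibration statements are
statistically meaningful.

## Known limitations

- The exact conditional test is a principled stand-in for
  replicate-aware NB machinery, not a reimplementation of it; its raw
  p-values are anti-conservative under over-dispersion (see above).
- TMM-style compositional normalisation, GSEA-ranked enrichment and
  probe-level microarray handling are out of scope.
- The inducible-gene list is user-supplied; no curated list ships with
  the package beyond the synthetic generator's planted one.
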