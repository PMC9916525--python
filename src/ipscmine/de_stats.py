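"""Differential expression against an unreplicated baseline, and gene-set
enrichment.

The study design is one fibroblast baseline sample versus several clonal
reprogrammed lines, each sequenced once.  With no replicates a
dispersion estimate is unavailable, so the per-gene test is the exact
conditional binomial test: conditional on the total count ``t = a + b``
of a gene in the (line, baseline) pair, ``a`` is Binomial(t, pi) under
the null of equal relative abundance, with ``pi`` the line's share of
the summed library sizes.  The two-sided p-value is the minimum-
likelihood tail: the sum of P(x) over all outcomes x whose probability
does not exceed the observed one.  This is the classical exact test for
a ratio of two Poisson rates; it assumes counts are Poisson-like within
a sample and is anti-conservative under strong extra-Poisson dispersion,
which is the price of the unreplicated design.

Fold changes are CPM ratios with a pseudocount of 1 added to the raw
counts before library scaling.  Multiple testing uses Benjamini-Hochberg
within each line (each line-versus-baseline comparison is its own
hypothesis family), and enrichment q-values are BH within each
annotation level.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ComputationError, InputError
from .io_formats import AnnotationCatalog, CountMatrix, normalize_symbol

logger = logging.getLogger(__name__)

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
DIRECTION_NS = "ns"

#: Relative tolerance for probability ties in the two-sided tail.
_TIE_RTOL = 1e-12


def cpm(count: float, library_size: float) -> float:
    """Counts per million: ``count * 1e6 / library_size``."""
    if library_size <= 0:
        raise ComputationError("library size must be positive")
    return count * 1e6 / library_size


def log2_fold_change(
    line_count: float,
    baseline_count: float,
    line_lib: float,
    baseline_lib: float,
    pseudocount: float = 1.0,
) -> float:
    """log2 CPM ratio (line over baseline) with pseudocount on raw counts."""
    if line_lib <= 0 or baseline_lib <= 0:
        raise ComputationError("library sizes must be positive")
    if pseudocount <= 0:
        raise ComputationError("pseudocount must be positive")
    num = (line_count + pseudocount) / line_lib
    den = (baseline_count + pseudocount) / baseline_lib
    return math.log2(num / den)


def exact_count_test(
    line_count: int,
    baseline_count: int,
    line_lib: float,
    baseline_lib: float,
) -> float:
    """Two-sided exact conditional binomial test for one (line, baseline) pair.

    Under H0, conditional on ``t = line_count + baseline_count``,
    ``line_count ~ Binomial(t, pi)`` with
    ``pi = line_lib / (line_lib + baseline_lib)``.  The p-value sums the
    probabilities of every outcome no more likely than the observed one
    (ties included up to a 1e-12 relative tolerance).  Returns 1.0 when
    t = 0.
    """
    a, b = line_count, baseline_count
    if a != int(a) or b != int(b) or a < 0 or b < 0:
        raise InputError("counts must be non-negative integers")
    if line_lib <= 0 or baseline_lib <= 0:
        raise ComputationError("library sizes must be positive")
    t = int(a) + int(b)
    if t == 0:
        return 1.0
    pi = line_lib / (line_lib + baseline_lib)
    pmf = stats.binom.pmf(np.arange(t + 1), t, pi)
    return _minlik_tail(pmf, int(a))


def _minlik_tail(pmf: np.ndarray, a: int) -> float:
    """Sum of outcome probabilities no larger than the observed one.

    When every outcome qualifies (the observed value is the mode up to
    ties) the p-value is exactly 1, avoiding float summation shortfall.
    """
    mask = pmf <= pmf[a] * (1.0 + _TIE_RTOL)
    if mask.all():
        return 1.0
    return min(float(pmf[mask].sum()), 1.0)


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    matrix: CountMatrix,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
    significance_on: str = "q",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-line differential expression table against the baseline.

    Returns one row per (gene, line) with columns ``gene_id, line_id,
    baseline_count, line_count, cpm_baseline, cpm_line, log2fc, p, q,
    direction``.  A gene is called ``up`` in a line when
    ``log2fc >= +lfc_threshold`` and the chosen significance measure
    (``p`` or ``q``; q is BH within the line) is below ``alpha``;
    symmetrically for ``down``.  Baseline replicate columns, if present,
    are pooled by summation.
    """
    if significance_on not in ("p", "q"):
        raise InputError("significance_on must be 'p' or 'q'")
    lines = matrix.line_samples
    if not lines:
        raise InputError("count matrix has no reprogrammed line samples")
    lib = matrix.library_sizes
    base_cols = matrix.baseline_samples
    base_counts = matrix.counts[base_cols].sum(axis=1).to_numpy()
    base_lib = float(lib[base_cols].sum())
    genes = np.array(matrix.gene_ids)

    frames = []
    for line in lines:
        a = matrix.counts[line].to_numpy()
        line_lib = float(lib[line])
        pvals = _exact_test_vector(a, base_counts, line_lib, base_lib)
        qvals = bh_adjust(pvals)
        with np.errstate(divide="ignore"):
            lfc = np.log2(
                ((a + pseudocount) / line_lib)
                / ((base_counts + pseudocount) / base_lib)
            )
        sig = pvals < alpha if significance_on == "p" else qvals < alpha
        direction = np.where(
            sig & (lfc >= lfc_threshold),
            DIRECTION_UP,
            np.where(sig & (lfc <= -lfc_threshold), DIRECTION_DOWN, DIRECTION_NS),
        )
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": genes,
                    "line_id": line,
                    "baseline_count": base_counts,
                    "line_count": a,
                    "cpm_baseline": base_counts * 1e6 / base_lib,
                    "cpm_line": a * 1e6 / line_lib,
                    "log2fc": lfc,
                    "p": pvals,
                    "q": qvals,
                    "direction": direction,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _exact_test_vector(
    a: np.ndarray, b: np.ndarray, line_lib: float, baseline_lib: float
) -> np.ndarray:
    """Vector of exact conditional p-values, one per gene.

    Outcomes are grouped by total so the Binomial pmf over 0..t is
    evaluated once per distinct total.
    """
    pi = line_lib / (line_lib + baseline_lib)
    totals = a + b
    p = np.ones(len(a))
    order = np.argsort(totals)
    pmf: np.ndarray | None = None
    cached_t = -1
    for idx in order:
        t = int(totals[idx])
        if t == 0:
            continue
        if t != cached_t:
            pmf = stats.binom.pmf(np.arange(t + 1), t, pi)
            cached_t = t
        p[idx] = _minlik_tail(pmf, int(a[idx]))
    return p


def upregulated_genes(de: pd.DataFrame, min_up_lines: int = 1) -> frozenset[str]:
    """Genes called up in at least ``min_up_lines`` lines."""
    up = de[de["direction"] == DIRECTION_UP]
    counts = up.groupby("gene_id")["line_id"].nunique()
    return frozenset(counts[counts >= min_up_lines].index)


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------


def enrich(
    query: Iterable[str],
    catalog: AnnotationCatalog,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in every catalog term.

    For a term with K members in the universe of size N and a query of
    size n overlapping it in k genes, ``p = P(X >= k)`` for
    X ~ Hypergeometric(N, K, n).  q-values are BH within each level.
    Terms disjoint from the universe are skipped with a warning.
    """
    universe = frozenset(normalize_symbol(g) for g in universe)
    if not universe:
        raise InputError("empty gene universe")
    query = frozenset(normalize_symbol(g) for g in query)
    stray = query - universe
    if stray:
        raise InputError(
            f"query genes outside the universe: {sorted(stray)[:5]}..."
            if len(stray) > 5
            else f"query genes outside the universe: {sorted(stray)}"
        )
    N, n = len(universe), len(query)
    rows = []
    for level in catalog.levels():
        for tid, term in catalog.terms(level).items():
            members = term.genes & universe
            if not members:
                logger.warning(
                    "term %s (%s) disjoint from universe; skipped", tid, level
                )
                continue
            K = len(members)
            k = len(query & members)
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            rows.append(
                {
                    "level": level,
                    "term_id": tid,
                    "term_name": term.name,
                    "overlap": k,
                    "term_size": K,
                    "query_size": n,
                    "universe_size": N,
                    "p": min(p, 1.0),
                    "overlap_genes": ",".join(sorted(query & members)),
                }
            )
    result = pd.DataFrame(
        rows,
        columns=[
            "level",
            "term_id",
            "term_name",
            "overlap",
            "term_size",
            "query_size",
            "universe_size",
            "p",
            "overlap_genes",
        ],
    )
    if result.empty:
        result["q"] = pd.Series(dtype=float)
        return result
    result["q"] = np.nan
    for level, idx in result.groupby("level").groups.items():
        result.loc[idx, "q"] = bh_adjust(result.loc[idx, "p"].to_numpy())
    return result


GO_LEVELS = ("GO-component", "GO-function", "GO-process")
PATHWAY_LEVELS = ("KEGG-A", "KEGG-B", "KEGG-pathway")

#: Stemness-related pathways always carried into the selection, after the
#: practice of force-including pathways with known roles in reprogramming
#: (pluripotency regulation, PI3K, MAPK, Wnt, JAK-STAT, TGF-beta,
#: apoptosis, oxidative phosphorylation) regardless of their q-value.
DEFAULT_STEMNESS_PATHWAYS = (
    "APOPTOSIS",
    "OXIDATIVE_PHOSPHORYLATION",
    "PLURIPOTENCY_REGULATION",
    "PI3K_AKT_SIGNALING",
    "MAPK_SIGNALING",
    "WNT_SIGNALING",
    "JAK_STAT_SIGNALING",
    "TGF_BETA_SIGNALING",
)


def select_top_terms(
    enrichment: pd.DataFrame,
    go_top_n: int = 20,
    pathway_q: float = 0.05,
    always_include: Sequence[str] = (),
) -> pd.DataFrame:
    """Select the terms that feed the group-1 screen.

    GO levels: the ``go_top_n`` smallest-p terms per level (ties broken
    by larger overlap, then term id).  Pathway (KEGG) levels: all terms
    with q < ``pathway_q``, unioned with ``always_include`` (forced
    terms are flagged ``forced``).  Returns the selected enrichment rows
    plus ``selection`` in {top_go, q_pathway, forced}.
    """
    if enrichment.empty:
        return enrichment.assign(selection=pd.Series(dtype=str))
    chunks = []
    for level, sub in enrichment.groupby("level"):
        if level in GO_LEVELS:
            ranked = sub.sort_values(
                ["p", "overlap", "term_id"], ascending=[True, False, True]
            ).head(go_top_n)
            chunks.append(ranked.assign(selection="top_go"))
        else:
            hits = sub[sub["q"] < pathway_q].assign(selection="q_pathway")
            chunks.append(hits)
            wanted = {t for t in always_include} - set(hits["term_id"])
            forced = sub[sub["term_id"].isin(wanted)].assign(selection="forced")
            chunks.append(forced)
    known = set(enrichment["term_id"])
    for term in always_include:
        if term not in known:
            logger.warning("always-include term %r not in catalog; skipped", term)
    out = pd.concat(chunks, ignore_index=True)
    return out.sort_values(["level", "p", "term_id"]).reset_index(drop=True)
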