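"""The three candidate screens sharing one count filter.

Group 1 starts from enrichment: up-regulated genes belonging to at least
one selected term (top GO terms plus significant/forced pathways).
Group 2 starts from known biology: annotation subdatasets that hold the
detected inducible genes, then their up-regulated members.  Group 3 is
the unscreened supplement: all up-regulated genes passing the count
filter, ranked per line by raw count, top-k per line, unioned.

All three apply the same abundance filter: baseline count at most
``max_baseline`` (default 50: expressed at most weakly in fibroblasts)
and line counts at least ``min_line`` (default 20: solidly detected in
the reprogrammed lines) under a configurable aggregation across lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .de_stats import DIRECTION_UP, upregulated_genes
from .errors import InputError
from .io_formats import AnnotationCatalog, CountMatrix, GeneList, normalize_symbol

logger = logging.getLogger(__name__)

GROUP1 = "group1"
GROUP2 = "group2"
GROUP3 = "group3_supplementary"

AGGREGATIONS = ("all_lines", "any_line", "mean", "at_least_k")


@dataclass(frozen=True)
class CountFilterSpec:
    """Abundance thresholds: baseline <= max_baseline, lines >= min_line.

    ``aggregation`` decides how the per-line condition is pooled across
    the reprogrammed lines; ``k`` is used by ``at_least_k`` only.
    """

    max_baseline: int = 50
    min_line: int = 20
    aggregation: str = "mean"
    k: int = 1

    def validate(self, n_lines: int) -> None:
        if self.max_baseline < 0 or self.min_line < 0:
            raise InputError("count thresholds must be non-negative")
        if self.aggregation not in AGGREGATIONS:
            raise InputError(
                f"aggregation must be one of {AGGREGATIONS}, got {self.aggregation!r}"
            )
        if self.aggregation == "at_least_k" and not 1 <= self.k <= n_lines:
            raise InputError("k must satisfy 1 <= k <= number of lines")


@dataclass(frozen=True)
class ScreenSet:
    """A named screen outcome with per-gene provenance."""

    label: str
    genes: frozenset[str]
    provenance: Mapping[str, dict]
    parameters: Mapping[str, object]

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene in sorted(self.genes):
            prov = self.provenance.get(gene, {})
            rows.append(
                {
                    "gene_id": gene,
                    **{
                        key: ",".join(map(str, val)) if isinstance(val, (list, tuple, set, frozenset)) else val
                        for key, val in sorted(prov.items())
                    },
                }
            )
        return pd.DataFrame(rows)


def count_filter(
    genes: Iterable[str], matrix: CountMatrix, spec: CountFilterSpec
) -> frozenset[str]:
    """Genes passing baseline <= max_baseline and the line-count rule.

    Baseline replicate columns, if present, are pooled by their mean.
    Deterministic and idempotent.
    """
    spec.validate(len(matrix.line_samples))
    genes = [normalize_symbol(g) for g in genes]
    universe = matrix.gene_universe()
    unknown = [g for g in genes if g not in universe]
    if unknown:
        raise InputError(f"gene(s) not in count matrix: {unknown[:5]}")
    if not genes:
        return frozenset()
    base = matrix.counts.loc[genes, matrix.baseline_samples].mean(axis=1)
    lines = matrix.counts.loc[genes, matrix.line_samples]
    ok_base = base <= spec.max_baseline
    meets = lines.ge(spec.min_line)
    if spec.aggregation == "all_lines":
        ok_line = meets.all(axis=1)
    elif spec.aggregation == "any_line":
        ok_line = meets.any(axis=1)
    elif spec.aggregation == "mean":
        ok_line = lines.mean(axis=1) >= spec.min_line
    else:  # at_least_k
        ok_line = meets.sum(axis=1) >= spec.k
    return frozenset(np.array(genes)[(ok_base & ok_line).to_numpy()])


def _up_evidence(de: pd.DataFrame, genes: frozenset[str]) -> dict[str, dict]:
    """Per-gene record of the lines, counts and fold changes behind an up call."""
    sub = de[(de["gene_id"].isin(genes)) & (de["direction"] == DIRECTION_UP)]
    out: dict[str, dict] = {}
    for gene, grp in sub.groupby("gene_id"):
        out[gene] = {
            "up_lines": sorted(grp["line_id"]),
            "n_up_lines": int(grp["line_id"].nunique()),
            "max_log2fc": float(grp["log2fc"].max()),
            "baseline_count": int(grp["baseline_count"].iloc[0]),
            "mean_line_count": float(grp["line_count"].mean()),
        }
    return out


def group1_screen(
    de: pd.DataFrame,
    selected_terms: pd.DataFrame,
    catalog: AnnotationCatalog,
    matrix: CountMatrix,
    spec: CountFilterSpec,
    min_up_lines: int = 1,
) -> ScreenSet:
    """Enrichment-driven screen: selected-term members, up-regulated,
    passing the count filter."""
    params = {
        "min_up_lines": min_up_lines,
        **asdict(spec),
        "n_selected_terms": 0 if selected_terms is None else len(selected_terms),
    }
    if selected_terms is None or selected_terms.empty:
        logger.warning("group1: no selected terms; screen is empty")
        return ScreenSet(GROUP1, frozenset(), {}, params)
    term_members: dict[str, frozenset[str]] = {}
    for _, row in selected_terms.iterrows():
        term = catalog.terms(row["level"]).get(row["term_id"])
        if term is not None:
            term_members[row["term_id"]] = term.genes
    member_union = frozenset().union(*term_members.values()) if term_members else frozenset()
    up = upregulated_genes(de, min_up_lines)
    candidates = (member_union & up) & matrix.gene_universe()
    passed = count_filter(candidates, matrix, spec)
    prov = _up_evidence(de, passed)
    for gene in passed:
        prov.setdefault(gene, {})["terms"] = sorted(
            tid for tid, members in term_members.items() if gene in members
        )
    return ScreenSet(GROUP1, passed, prov, params)


def select_main_subdatasets(
    inducible: GeneList,
    catalog: AnnotationCatalog,
    detected: Iterable[str],
    min_inducible_per_term: Mapping[str, int] | int | None = None,
) -> pd.DataFrame:
    """Annotation subdatasets holding the detected inducible genes.

    ``detected`` is the gene universe of the count matrix; only inducible
    genes present there count.  Per level, a term qualifies when it holds
    at least ``min_inducible_per_term`` detected inducible genes (default
    3 at GO levels, 2 at KEGG levels).  Returns the qualifying terms
    ranked by inducible coverage, with the hit genes as provenance.
    """
    detected_set = frozenset(normalize_symbol(g) for g in detected)
    hits = inducible.as_set() & detected_set
    if not hits:
        logger.warning("no inducible gene detected in the count matrix")
        return pd.DataFrame(
            columns=["level", "term_id", "n_inducible", "inducible_genes"]
        )
    if min_inducible_per_term is None:
        min_per_level = {
            lvl: (2 if lvl.startswith("KEGG") else 3) for lvl in catalog.levels()
        }
    elif isinstance(min_inducible_per_term, int):
        min_per_level = {lvl: min_inducible_per_term for lvl in catalog.levels()}
    else:
        min_per_level = dict(min_inducible_per_term)
    rows = []
    for level in catalog.levels():
        threshold = min_per_level.get(level, 1)
        for tid, term in catalog.terms(level).items():
            overlap = term.genes & hits
            if len(overlap) >= threshold:
                rows.append(
                    {
                        "level": level,
                        "term_id": tid,
                        "n_inducible": len(overlap),
                        "inducible_genes": ",".join(sorted(overlap)),
                    }
                )
    out = pd.DataFrame(rows, columns=["level", "term_id", "n_inducible", "inducible_genes"])
    return out.sort_values(
        ["level", "n_inducible", "term_id"], ascending=[True, False, True]
    ).reset_index(drop=True)


def group2_screen(
    de: pd.DataFrame,
    selected_subdatasets: pd.DataFrame,
    catalog: AnnotationCatalog,
    matrix: CountMatrix,
    spec: CountFilterSpec,
    min_up_lines: int = 1,
) -> ScreenSet:
    """Known-gene-driven screen: members of the inducible-bearing
    subdatasets, up-regulated, passing the count filter."""
    params = {
        "min_up_lines": min_up_lines,
        **asdict(spec),
        "n_subdatasets": 0 if selected_subdatasets is None else len(selected_subdatasets),
    }
    if selected_subdatasets is None or selected_subdatasets.empty:
        logger.warning("group2: no selected subdatasets; screen is empty")
        return ScreenSet(GROUP2, frozenset(), {}, params)
    members: dict[str, frozenset[str]] = {}
    for _, row in selected_subdatasets.iterrows():
        term = catalog.terms(row["level"]).get(row["term_id"])
        if term is not None:
            members[row["term_id"]] = term.genes
    union = frozenset().union(*members.values()) if members else frozenset()
    up = upregulated_genes(de, min_up_lines)
    candidates = (union & up) & matrix.gene_universe()
    passed = count_filter(candidates, matrix, spec)
    prov = _up_evidence(de, passed)
    for gene in passed:
        prov.setdefault(gene, {})["subdatasets"] = sorted(
            tid for tid, genes in members.items() if gene in genes
        )
    return ScreenSet(GROUP2, passed, prov, params)


def group3_supplementary(
    de: pd.DataFrame,
    matrix: CountMatrix,
    spec: CountFilterSpec,
    top_k: int = 30,
    min_up_lines: int = 1,
) -> ScreenSet:
    """Supplementary screen: per line, the ``top_k`` highest-count
    qualifying up-regulated genes, unioned across lines.

    Ranking uses the line's raw count, descending; ties break on the
    uppercased gene id, ascending, so the rank-k boundary is
    deterministic.
    """
    up = upregulated_genes(de, min_up_lines)
    qualifying = count_filter(up & matrix.gene_universe(), matrix, spec)
    params = {"top_k": top_k, "min_up_lines": min_up_lines, **asdict(spec)}
    selected: set[str] = set()
    prov: dict[str, dict] = {}
    up_rows = de[de["direction"] == DIRECTION_UP]
    for line in matrix.line_samples:
        line_up = set(up_rows[up_rows["line_id"] == line]["gene_id"]) & qualifying
        ranked = sorted(
            line_up, key=lambda g: (-int(matrix.counts.at[g, line]), g)
        )[:top_k]
        for rank, gene in enumerate(ranked, start=1):
            selected.add(gene)
            rec = prov.setdefault(gene, {"lines": [], "ranks": [], "counts": []})
            rec["lines"].append(line)
            rec["ranks"].append(rank)
            rec["counts"].append(int(matrix.counts.at[gene, line]))
    return ScreenSet(GROUP3, frozenset(selected), prov, params)


def compare_groups(g1: ScreenSet, g2: ScreenSet) -> dict:
    """Overlap report for two screens; the merge decision stays with the
    caller."""
    inter = g1.genes & g2.genes
    union = g1.genes | g2.genes
    return {
        "label_1": g1.label,
        "label_2": g2.label,
        "size_1": len(g1.genes),
        "size_2": len(g2.genes),
        "intersection": len(inter),
        "union": len(union),
        "jaccard": (len(inter) / len(union)) if union else 1.0,
        "shared_genes": sorted(inter),
    }
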