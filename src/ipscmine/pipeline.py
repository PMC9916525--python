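"""End-to-end mining pipeline: DE -> enrichment -> screens -> network ->
candidate table.

``mine`` wires the stages together over in-memory objects; the CLI and
the simulation entry points are thin wrappers around it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import de_stats, network_core, screening
from .io_formats import AnnotationCatalog, CountMatrix, GeneList, PPINetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MineParams:
    """Every knob of the mining pipeline, with the study defaults."""

    lfc_threshold: float = 1.0
    alpha: float = 0.05
    significance_on: str = "q"
    go_top_n: int = 20
    pathway_q: float = 0.05
    always_include: Sequence[str] = ()
    max_baseline: int = 50
    min_line: int = 20
    aggregation: str = "mean"
    at_least_k: int = 1
    min_up_lines: int = 1
    top_k: int = 30
    min_component: int = 6
    min_degree: int = 4


@dataclass
class MineResult:
    """All intermediate and final outputs of one mining run."""

    de: pd.DataFrame
    enrichment: pd.DataFrame
    selected_terms: pd.DataFrame
    subdatasets: pd.DataFrame
    group1: screening.ScreenSet
    group2: screening.ScreenSet
    group3: screening.ScreenSet
    group_overlap: dict
    components: list
    core: frozenset[str]
    core_info: pd.DataFrame
    candidates: pd.DataFrame
    stage_sizes: dict = field(default_factory=dict)


def mine(
    matrix: CountMatrix,
    catalog: AnnotationCatalog,
    ppi: PPINetwork,
    inducible: GeneList,
    params: MineParams = MineParams(),
) -> MineResult:
    """Run the full candidate-gene mining procedure.

    Stages: per-line exact-test DE; enrichment of the pooled up set and
    term selection; group-1 (enrichment-driven) and group-2
    (inducible-driven) screens plus the group-3 per-line top-k
    supplement; induction of the screened genes into the interaction
    network; component/degree core extraction; combination of core and
    supplementary genes into the candidate table.
    """
    spec = screening.CountFilterSpec(
        max_baseline=params.max_baseline,
        min_line=params.min_line,
        aggregation=params.aggregation,
        k=params.at_least_k,
    )
    de = de_stats.call_de(
        matrix,
        lfc_threshold=params.lfc_threshold,
        alpha=params.alpha,
        significance_on=params.significance_on,
    )
    universe = matrix.gene_universe()
    up_any = de_stats.upregulated_genes(de, params.min_up_lines)
    enrichment = de_stats.enrich(up_any, catalog, universe)
    selected_terms = de_stats.select_top_terms(
        enrichment,
        go_top_n=params.go_top_n,
        pathway_q=params.pathway_q,
        always_include=params.always_include,
    )
    group1 = screening.group1_screen(
        de, selected_terms, catalog, matrix, spec, params.min_up_lines
    )
    subdatasets = screening.select_main_subdatasets(inducible, catalog, universe)
    group2 = screening.group2_screen(
        de, subdatasets, catalog, matrix, spec, params.min_up_lines
    )
    group3 = screening.group3_supplementary(
        de, matrix, spec, top_k=params.top_k, min_up_lines=params.min_up_lines
    )
    overlap = screening.compare_groups(group1, group2)

    screened = group1.genes | group2.genes
    induced = network_core.induced_network(screened, ppi)
    components = network_core.filter_components(induced, params.min_component)
    core = network_core.core_genes(components, params.min_degree)
    core_info = network_core.core_gene_table(components, params.min_degree)

    membership: dict[str, set[str]] = {}
    for label, sset in (
        ("group1", group1),
        ("group2", group2),
        ("group3", group3),
    ):
        for gene in sset.genes:
            membership.setdefault(gene, set()).add(label)
    candidates = network_core.combine_candidates(
        core,
        group3.genes,
        core_info=core_info,
        de=de,
        matrix=matrix,
        group_membership=membership,
    )
    sizes = {
        "genes": len(universe),
        "lines": len(matrix.line_samples),
        "upregulated": len(up_any),
        "selected_terms": len(selected_terms),
        "group1": len(group1),
        "group2": len(group2),
        "supplementary": len(group3),
        "components": len(components),
        "core": len(core),
        "final": len(candidates),
    }
    for stage, size in sizes.items():
        logger.info("stage %s: %d", stage, size)
    return MineResult(
        de=de,
        enrichment=enrichment,
        selected_terms=selected_terms,
        subdatasets=subdatasets,
        group1=group1,
        group2=group2,
        group3=group3,
        group_overlap=overlap,
        components=components,
        core=core,
        core_info=core_info,
        candidates=candidates,
        stage_sizes=sizes,
    )
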