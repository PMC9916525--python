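"""Core-gene extraction from interaction evidence and the final
candidate table.

Core genes are hubs of the query-induced interaction network: the
induced subgraph is split into connected components, components with
fewer than ``min_size`` proteins (default 6) are discarded, and within
each retained component the nodes with degree >= ``min_degree`` (default
4, i.e. "more than three connections") are the core.  Degree is counted
inside the retained component, not in the full background graph.

The final candidate set is the union of the core genes and the
supplementary (per-line top-k) genes, each row labelled ``core``,
``supplementary`` or ``both``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .io_formats import CountMatrix, PPINetwork, normalize_symbol

logger = logging.getLogger(__name__)

SOURCE_CORE = "core"
SOURCE_SUPPLEMENTARY = "supplementary"
SOURCE_BOTH = "both"


@dataclass(frozen=True)
class Component:
    """A retained connected component with a stable id."""

    component_id: int
    members: frozenset[str]
    graph: nx.Graph

    def __len__(self) -> int:
        return len(self.members)


def induced_network(genes: Iterable[str], ppi: PPINetwork) -> PPINetwork:
    """Subgraph induced on the query genes.

    Queried genes absent from the background are ignored; queried genes
    present but unconnected are kept as degree-0 nodes.
    """
    query = {normalize_symbol(g) for g in genes}
    if not query:
        logger.warning("empty gene query; induced network is empty")
        return PPINetwork(graph=nx.Graph())
    keep = query & ppi.nodes
    return PPINetwork(graph=nx.Graph(ppi.graph.subgraph(keep)))


def filter_components(network: PPINetwork, min_size: int = 6) -> list[Component]:
    """Connected components with >= min_size nodes (inclusive).

    Ids are assigned by size descending, then smallest member id, so
    they are stable across runs.
    """
    comps = [frozenset(c) for c in nx.connected_components(network.graph)]
    kept = [c for c in comps if len(c) >= min_size]
    kept.sort(key=lambda c: (-len(c), min(c)))
    return [
        Component(cid, members, nx.Graph(network.graph.subgraph(members)))
        for cid, members in enumerate(kept, start=1)
    ]


def core_genes(components: Iterable[Component], min_degree: int = 4) -> frozenset[str]:
    """Nodes with degree >= min_degree within their retained component."""
    out: set[str] = set()
    for comp in components:
        out |= {n for n, d in comp.graph.degree if d >= min_degree}
    return frozenset(out)


def core_gene_table(
    components: Iterable[Component], min_degree: int = 4
) -> pd.DataFrame:
    """Per-gene component id and within-component degree for core genes."""
    rows = []
    for comp in components:
        for node, deg in comp.graph.degree:
            if deg >= min_degree:
                rows.append(
                    {"gene_id": node, "component_id": comp.component_id, "degree": deg}
                )
    return pd.DataFrame(rows, columns=["gene_id", "component_id", "degree"])


def combine_candidates(
    core: Iterable[str],
    supplementary: Iterable[str],
    core_info: pd.DataFrame | None = None,
    de: pd.DataFrame | None = None,
    matrix: CountMatrix | None = None,
    group_membership: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Union the core and supplementary sets into the candidate table.

    The row count always satisfies
    ``|core| + |supplementary| - |core & supplementary|``; genes in both
    sets get source ``both``.  Optional evidence (degree/component from
    ``core_info``, per-line counts and mean log2fc from ``de``/``matrix``,
    qualifying screens from ``group_membership``) is attached when given.
    Rows sort ``both`` first, then degree descending, then gene id.
    """
    core_set = frozenset(normalize_symbol(g) for g in core)
    supp_set = frozenset(normalize_symbol(g) for g in supplementary)
    info = (
        core_info.set_index("gene_id")
        if core_info is not None and not core_info.empty
        else pd.DataFrame(columns=["component_id", "degree"])
    )
    mean_lfc: dict[str, float] = {}
    if de is not None and not de.empty:
        mean_lfc = de.groupby("gene_id")["log2fc"].mean().to_dict()
    rows = []
    for gene in sorted(core_set | supp_set):
        if gene in core_set and gene in supp_set:
            source = SOURCE_BOTH
        elif gene in core_set:
            source = SOURCE_CORE
        else:
            source = SOURCE_SUPPLEMENTARY
        row: dict = {"gene_id": gene, "source": source}
        if gene in info.index:
            row["component_id"] = int(info.at[gene, "component_id"])
            row["degree"] = int(info.at[gene, "degree"])
        else:
            row["component_id"] = pd.NA
            row["degree"] = pd.NA
        row["mean_log2fc"] = mean_lfc.get(gene, float("nan"))
        if matrix is not None and gene in matrix.gene_universe():
            for line in matrix.line_samples:
                row[f"count_{line}"] = int(matrix.counts.at[gene, line])
        if group_membership is not None:
            row["groups"] = ",".join(sorted(group_membership.get(gene, ())))
        rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        return pd.DataFrame(
            columns=["gene_id", "source", "component_id", "degree", "mean_log2fc"]
        )
    source_rank = {SOURCE_BOTH: 0, SOURCE_CORE: 1, SOURCE_SUPPLEMENTARY: 1}
    table["_rank"] = table["source"].map(source_rank)
    table["_deg"] = pd.to_numeric(table["degree"], errors="coerce").fillna(-1)
    table = (
        table.sort_values(["_rank", "_deg", "gene_id"], ascending=[True, False, True])
        .drop(columns=["_rank", "_deg"])
        .reset_index(drop=True)
    )
    return table
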