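"""Readers, writers and validated containers for every external format.

All gene identity is the *uppercased* symbol string; every reader
normalizes on ingest so joins across sources (count matrix, GMT catalogs,
STRING-style edge tables, ortholog maps) are case-insensitive.

Formats
-------
- count matrix: TSV, first column ``gene_id``, one column per sample,
  plus a roles sidecar TSV (``sample_id``, ``role`` in {baseline, line});
- gene-set catalogs: one GMT file per annotation level
  (``term_id<TAB>description<TAB>gene...``);
- interaction network: STRING detailed-format dialect
  (``protein1<TAB>protein2<TAB>combined_score``, scores 0-1000);
- gene lists: plain text, one symbol per line, ``#`` comments allowed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import FormatError, InputError

logger = logging.getLogger(__name__)

ROLE_BASELINE = "baseline"
ROLE_LINE = "line"

#: The six annotation levels, in canonical order.
LEVELS = (
    "KEGG-A",
    "KEGG-B",
    "KEGG-pathway",
    "GO-component",
    "GO-function",
    "GO-process",
)


def normalize_symbol(symbol: str) -> str:
    """Canonical gene identity: stripped, uppercased symbol."""
    return symbol.strip().upper()


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountMatrix:
    """Integer gene x sample count matrix with sample roles.

    ``counts`` is genes-as-rows; the index holds unique uppercased gene
    ids and the columns hold sample ids.  ``roles`` maps every sample to
    ``"baseline"`` or ``"line"``.  Library sizes are always the column
    sums; they are recomputed, never stored.
    """

    counts: pd.DataFrame
    roles: Mapping[str, str]

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        if counts.columns.has_duplicates:
            raise FormatError("duplicate sample ids in count matrix")
        missing = [s for s in counts.columns if s not in self.roles]
        if missing:
            raise FormatError(f"no role declared for sample(s): {missing}")
        bad_roles = {
            s: r
            for s, r in self.roles.items()
            if r not in (ROLE_BASELINE, ROLE_LINE)
        }
        if bad_roles:
            raise FormatError(f"unknown sample role(s): {bad_roles}")
        if not all(pd.api.types.is_integer_dtype(d) for d in counts.dtypes):
            raise FormatError("counts must be integers")
        if (counts.to_numpy() < 0).any():
            raise FormatError("counts must be non-negative")
        if not self.baseline_samples:
            raise FormatError("count matrix has no baseline sample")
        if not self.line_samples:
            raise FormatError("count matrix has no reprogrammed line sample")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def baseline_samples(self) -> list[str]:
        return [s for s in self.counts.columns if self.roles[s] == ROLE_BASELINE]

    @property
    def line_samples(self) -> list[str]:
        return [s for s in self.counts.columns if self.roles[s] == ROLE_LINE]

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def gene_universe(self) -> frozenset[str]:
        return frozenset(self.counts.index)


def read_count_matrix(path: str | Path, roles_path: str | Path) -> CountMatrix:
    """Read a TSV count matrix plus its sample-role sidecar.

    Rejects negative, non-integer or duplicated-gene rows with a
    :class:`FormatError` naming the offender.
    """
    path, roles_path = Path(path), Path(roles_path)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse count matrix {path}: {exc}") from exc
    if raw.columns[0] != "gene_id":
        raise FormatError(
            f"{path}: first column must be 'gene_id', got {raw.columns[0]!r}"
        )
    genes = raw["gene_id"].map(normalize_symbol)
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicated gene row {dup!r}")
    body = raw.drop(columns="gene_id")
    numeric = body.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        gene = genes[numeric.isna().any(axis=1)].iloc[0]
        raise FormatError(f"{path}: non-numeric count in gene {gene!r}")
    if ((numeric % 1) != 0).any().any():
        gene = genes[((numeric % 1) != 0).any(axis=1)].iloc[0]
        raise FormatError(f"{path}: non-integer count in gene {gene!r}")
    if (numeric < 0).any().any():
        gene = genes[(numeric < 0).any(axis=1)].iloc[0]
        raise FormatError(f"{path}: negative count in gene {gene!r}")
    counts = numeric.astype("int64")
    counts.index = pd.Index(genes, name="gene_id")

    roles_df = pd.read_csv(roles_path, sep="\t", dtype=str)
    for col in ("sample_id", "role"):
        if col not in roles_df.columns:
            raise FormatError(f"{roles_path}: missing column {col!r}")
    roles = dict(zip(roles_df["sample_id"], roles_df["role"]))
    return CountMatrix(counts=counts, roles=roles)


def write_count_matrix(
    matrix: CountMatrix, path: str | Path, roles_path: str | Path
) -> None:
    out = matrix.counts.copy()
    out.insert(0, "gene_id", out.index)
    out.to_csv(path, sep="\t", index=False)
    pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "role": [matrix.roles[s] for s in matrix.sample_ids],
        }
    ).to_csv(roles_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# AnnotationCatalog
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Term:
    term_id: str
    name: str
    genes: frozenset[str]


@dataclass
class AnnotationCatalog:
    """Six-level term -> gene-set mapping (KEGG A/B/pathway, GO C/F/P)."""

    entries: dict[str, dict[str, Term]] = field(
        default_factory=lambda: {lvl: {} for lvl in LEVELS}
    )

    def add(self, level: str, term_id: str, name: str, genes: Iterable[str]) -> None:
        if level not in self.entries:
            raise InputError(f"unknown annotation level {level!r}")
        genes = frozenset(normalize_symbol(g) for g in genes if g.strip())
        if not genes:
            raise FormatError(f"term {term_id!r} ({level}) has an empty gene set")
        if term_id in self.entries[level]:
            raise FormatError(f"duplicate term id {term_id!r} in level {level}")
        self.entries[level][term_id] = Term(term_id, name, genes)

    def levels(self) -> tuple[str, ...]:
        return LEVELS

    def terms(self, level: str) -> dict[str, Term]:
        if level not in self.entries:
            raise InputError(f"unknown annotation level {level!r}")
        return self.entries[level]

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for level_terms in self.entries.values():
            for term in level_terms.values():
                out |= term.genes
        return frozenset(out)

    def terms_containing(self, level: str, gene: str) -> list[str]:
        gene = normalize_symbol(gene)
        return [
            tid for tid, term in self.terms(level).items() if gene in term.genes
        ]


def read_gmt(path: str | Path, level: str) -> AnnotationCatalog:
    """Read one GMT file into a single-level catalog fragment."""
    catalog = AnnotationCatalog()
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3"
                )
            term_id, desc, *genes = fields
            catalog.add(level, term_id, desc, genes)
    return catalog


def read_gmt_dir(gmt_dir: str | Path) -> AnnotationCatalog:
    """Read the six per-level GMT files ``<level>.gmt`` from a directory."""
    gmt_dir = Path(gmt_dir)
    catalog = AnnotationCatalog()
    for level in LEVELS:
        path = gmt_dir / f"{level}.gmt"
        if not path.exists():
            raise FormatError(f"missing GMT file for level {level}: {path}")
        fragment = read_gmt(path, level)
        for term in fragment.terms(level).values():
            catalog.add(level, term.term_id, term.name, term.genes)
    return catalog


def write_gmt_dir(catalog: AnnotationCatalog, gmt_dir: str | Path) -> None:
    gmt_dir = Path(gmt_dir)
    gmt_dir.mkdir(parents=True, exist_ok=True)
    for level in LEVELS:
        with open(gmt_dir / f"{level}.gmt", "w", encoding="utf-8") as fh:
            for tid in sorted(catalog.terms(level)):
                term = catalog.terms(level)[tid]
                genes = "\t".join(sorted(term.genes))
                fh.write(f"{term.term_id}\t{term.name}\t{genes}\n")


# ---------------------------------------------------------------------------
# PPINetwork
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PPINetwork:
    """Undirected confidence-scored interaction graph over gene symbols.

    Backed by a :class:`networkx.Graph`; every edge carries a ``score``
    attribute in [0, 1000].  No self-loops, no parallel edges.
    """

    graph: nx.Graph

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise InputError(f"self-loop on {u!r}")
            score = data.get("score")
            if score is None or not 0 <= score <= 1000:
                raise InputError(f"edge {u}-{v} score {score!r} outside [0, 1000]")

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, gene: str) -> int:
        return int(self.graph.degree[normalize_symbol(gene)])


def read_ppi_edges(path: str | Path, min_score: float = 400) -> PPINetwork:
    """Read a STRING-detailed-style edge table, keeping score >= min_score.

    Pairs are canonicalized (A-B == B-A; the higher score wins on
    duplicates) and self-loops are dropped with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    for col in ("protein1", "protein2", "combined_score"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    scores = pd.to_numeric(df["combined_score"], errors="coerce")
    if scores.isna().any():
        bad = df["combined_score"][scores.isna()].iloc[0]
        raise FormatError(f"{path}: non-numeric combined_score {bad!r}")
    graph = nx.Graph()
    n_loops = 0
    for p1, p2, score in zip(df["protein1"], df["protein2"], scores):
        a, b = normalize_symbol(p1), normalize_symbol(p2)
        if a == b:
            n_loops += 1
            continue
        if score < min_score:
            continue
        if graph.has_edge(a, b):
            graph[a][b]["score"] = max(graph[a][b]["score"], float(score))
        else:
            graph.add_edge(a, b, score=float(score))
    if n_loops:
        logger.warning("%s: dropped %d self-loop edge(s)", path, n_loops)
    return PPINetwork(graph=graph)


def write_ppi_edges(network: PPINetwork, path: str | Path) -> None:
    rows = sorted(
        (min(u, v), max(u, v), data["score"])
        for u, v, data in network.graph.edges(data=True)
    )
    pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# GeneList
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneList:
    """Ordered, case-normalized, duplicate-free gene symbol list."""

    symbols: tuple[str, ...]
    source_label: str = ""

    @classmethod
    def from_symbols(cls, symbols: Iterable[str], source_label: str = "") -> "GeneList":
        seen: dict[str, None] = {}
        for sym in symbols:
            norm = normalize_symbol(sym)
            if norm:
                seen.setdefault(norm, None)
        return cls(symbols=tuple(seen), source_label=source_label)

    def __len__(self) -> int:
        return len(self.symbols)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.symbols)


def read_gene_list(path: str | Path, source_label: str | None = None) -> GeneList:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        symbols = [
            line.strip() for line in fh if line.strip() and not line.startswith("#")
        ]
    return GeneList.from_symbols(symbols, source_label or path.stem)


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sym in genes:
            fh.write(f"{normalize_symbol(sym)}\n")
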