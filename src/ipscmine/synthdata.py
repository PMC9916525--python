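"""Synthetic study generator with planted ground truth.

Emulates the study design the pipeline targets: one unreplicated
fibroblast baseline plus seven unreplicated clonal iPSC lines, a block
of genes up-regulated on reprogramming (the pluripotency programme), a
block down-regulated (the fibroblast programme), six-level annotation
catalogs whose designated terms are enriched for the up block, a
literature-style inducible-gene list drawn from the up block, and an
interaction network with a densely wired core inside the up block.

Counts are negative binomial.  Gene base abundances are log-normal;
per-sample expected counts are the library size times the gene's
relative abundance after the planted fold changes are applied, so
expected column totals equal the configured library sizes and planted
effects induce the same mild compositional shift real RNA-seq would
show.  The dispersion parameter follows the edgeR convention
(``var = mu + dispersion * mu**2``); the default 0.02 reflects clonal
cell lines with low biological variability.

Everything is a pure function of (config, seed): one master seed, with
fixed per-stage offsets for counts (+0), annotations (+1), the PPI graph
(+2) and the inducible list (+3).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_formats import LEVELS, AnnotationCatalog, CountMatrix, GeneList, PPINetwork

_SEED_OFFSET_COUNTS = 0
_SEED_OFFSET_ANNOTATIONS = 1
_SEED_OFFSET_PPI = 2
_SEED_OFFSET_INDUCIBLE = 3
_SEED_MOD = 2**31


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the eight-sample design (1 baseline + 7 lines) at a
    desk-scale gene universe of 2000 with a planted 100-gene up block, a
    100-gene down block at +/-3 log2 units, and a 6-gene complete
    interaction core inside the up block.
    """

    n_genes: int = 2000
    n_lines: int = 7
    n_baseline_replicates: int = 1
    seed: int = 0
    lib_size_baseline: int = 1_000_000
    lib_size_line: int = 1_000_000
    dispersion: float = 0.02
    base_mean_log_mean: float = 0.0
    base_mean_log_sd: float = 1.0
    n_planted_up: int = 100
    n_planted_down: int = 100
    up_log2fc: float = 3.0
    down_log2fc: float = -3.0
    planted_up_base_range: tuple[float, float] = (5.0, 30.0)
    n_terms_per_level: int = 20
    term_size_range: tuple[int, int] = (10, 50)
    n_enriched_terms_per_level: int = 3
    enriched_fraction: float = 0.8
    ppi_core_size: int = 6
    ppi_core_edge_prob: float = 1.0
    ppi_background_edge_prob: float = 0.003
    n_inducible: int = 25

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_lines <= 0 or self.n_baseline_replicates <= 0:
            raise ConfigError("n_genes, n_lines, n_baseline_replicates must be positive")
        if self.n_planted_up < 0 or self.n_planted_down < 0:
            raise ConfigError("planted block sizes must be non-negative")
        if self.n_planted_up + self.n_planted_down > self.n_genes:
            raise ConfigError("planted blocks exceed the gene universe")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        if self.lib_size_baseline <= 0 or self.lib_size_line <= 0:
            raise ConfigError("library sizes must be positive")
        lo, hi = self.term_size_range
        if lo < 1 or hi < lo:
            raise ConfigError("term_size_range must be 1 <= lo <= hi")
        if hi > self.n_genes:
            raise ConfigError("term sizes exceed the gene universe")
        if not 0 <= self.ppi_background_edge_prob <= 1:
            raise ConfigError("ppi_background_edge_prob must be a probability")
        if self.ppi_core_size < 2:
            raise ConfigError("ppi_core_size must be at least 2")
        # a null simulation (no up block) simply has no planted core
        if 0 < self.n_planted_up < self.ppi_core_size:
            raise ConfigError("ppi_core_size exceeds the planted up block")
        if self.n_inducible > self.n_planted_up:
            raise ConfigError("n_inducible exceeds the planted up block")


@dataclass(frozen=True)
class SimTruth:
    """Planted ground truth; the three gene categories partition the universe."""

    planted_up: frozenset[str]
    planted_down: frozenset[str]
    null_genes: frozenset[str]
    planted_core: frozenset[str]
    enriched_terms: frozenset[str]
    inducible_list: tuple[str, ...] = ()

    def to_json_dict(self) -> dict:
        return {
            "planted_up": sorted(self.planted_up),
            "planted_down": sorted(self.planted_down),
            "null_genes": sorted(self.null_genes),
            "planted_core": sorted(self.planted_core),
            "enriched_terms": sorted(self.enriched_terms),
            "inducible_list": list(self.inducible_list),
        }


def _rng(config: SimConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng((config.seed + offset) % _SEED_MOD)


def _gene_ids(n: int) -> list[str]:
    width = len(str(n - 1)) if n > 1 else 1
    return [f"G{i:0{width}d}" for i in range(n)]


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Draw the count matrix and its ground truth.

    The first ``n_planted_up`` gene slots (after a seeded shuffle) form
    the up block, the next ``n_planted_down`` the down block.  The core
    and inducible genes are seeded subsets of the up block, fixed here so
    annotation and network generation see the same truth.
    """
    config.validate()
    rng = _rng(config, _SEED_OFFSET_COUNTS)
    genes = _gene_ids(config.n_genes)

    perm = rng.permutation(config.n_genes)
    up_idx = perm[: config.n_planted_up]
    down_idx = perm[config.n_planted_up : config.n_planted_up + config.n_planted_down]
    planted_up = frozenset(genes[i] for i in up_idx)
    planted_down = frozenset(genes[i] for i in down_idx)
    null_genes = frozenset(genes) - planted_up - planted_down

    base_weight = rng.lognormal(
        mean=config.base_mean_log_mean,
        sigma=config.base_mean_log_sd,
        size=config.n_genes,
    )
    # Plant the up block on genes silent-to-weak in the baseline: a
    # pluripotency programme is off in fibroblasts, and the downstream
    # abundance filter (baseline <= max_baseline) presumes exactly that.
    # Weights are set so the expected *baseline* count of each up gene
    # equals a uniform draw from planted_up_base_range.
    if config.n_planted_up > 0:
        lo_c, hi_c = config.planted_up_base_range
        if not 0 < lo_c <= hi_c:
            raise ConfigError("planted_up_base_range must be 0 < lo <= hi")
        target = rng.uniform(lo_c, hi_c, size=config.n_planted_up)
        rest_mask = np.ones(config.n_genes, dtype=bool)
        rest_mask[up_idx] = False
        s_rest = base_weight[rest_mask].sum()
        total_target = target.sum()
        if total_target >= config.lib_size_baseline:
            raise ConfigError("planted_up_base_range too large for the library size")
        s_full = s_rest / (1.0 - total_target / config.lib_size_baseline)
        base_weight[up_idx] = target * s_full / config.lib_size_baseline
    fc = np.ones(config.n_genes)
    fc[up_idx] = 2.0**config.up_log2fc
    fc[down_idx] = 2.0**config.down_log2fc

    samples: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    r = 1.0 / config.dispersion  # NB shape

    def draw(weights: np.ndarray, lib_size: int) -> np.ndarray:
        mu = lib_size * weights / weights.sum()
        # numpy's NB: n successes, p; mean = n(1-p)/p  =>  p = r/(r+mu)
        return rng.negative_binomial(r, r / (r + mu))

    for b in range(config.n_baseline_replicates):
        name = "BCFF" if config.n_baseline_replicates == 1 else f"BCFF_{b + 1}"
        samples[name] = draw(base_weight, config.lib_size_baseline)
        roles[name] = "baseline"
    for j in range(config.n_lines):
        name = f"iPSC_L{j + 1:02d}"
        samples[name] = draw(base_weight * fc, config.lib_size_line)
        roles[name] = "line"

    counts = pd.DataFrame(samples, index=pd.Index(genes, name="gene_id")).astype(
        "int64"
    )
    matrix = CountMatrix(counts=counts, roles=roles)

    # Core: the ppi_core_size highest-abundance up genes (high counts keep
    # them detectable end to end); inducible: seeded sample of the up block.
    up_sorted = sorted(planted_up, key=lambda g: (-base_weight[genes.index(g)], g))
    planted_core = frozenset(up_sorted[: config.ppi_core_size]) if planted_up else frozenset()
    ind_rng = _rng(config, _SEED_OFFSET_INDUCIBLE)
    inducible = tuple(
        sorted(ind_rng.choice(sorted(planted_up), config.n_inducible, replace=False))
    )
    enriched_terms = frozenset(
        f"{lvl}:ENR{k:02d}"
        for lvl in LEVELS
        for k in range(config.n_enriched_terms_per_level)
    )
    truth = SimTruth(
        planted_up=planted_up,
        planted_down=planted_down,
        null_genes=null_genes,
        planted_core=planted_core,
        enriched_terms=enriched_terms,
        inducible_list=inducible,
    )
    return matrix, truth


def simulate_annotations(truth: SimTruth, config: SimConfig) -> AnnotationCatalog:
    """Six-level catalog whose designated terms over-draw from the up block.

    Enriched terms take ``enriched_fraction`` of their members from
    ``planted_up`` and the rest uniformly; background terms draw
    uniformly from the whole universe.  Every inducible gene is appended
    to the first enriched term of each level, guaranteeing per-level
    annotation coverage of the inducible list.
    """
    config.validate()
    rng = _rng(config, _SEED_OFFSET_ANNOTATIONS)
    universe = sorted(truth.planted_up | truth.planted_down | truth.null_genes)
    up = sorted(truth.planted_up)
    lo, hi = config.term_size_range
    catalog = AnnotationCatalog()
    for level in LEVELS:
        for k in range(config.n_terms_per_level):
            size = int(rng.integers(lo, hi + 1))
            term_id = f"{level}:ENR{k:02d}" if k < config.n_enriched_terms_per_level \
                else f"{level}:BG{k:02d}"
            if term_id in truth.enriched_terms and up:
                n_up = min(int(round(config.enriched_fraction * size)), len(up))
                members = set(rng.choice(up, n_up, replace=False))
                rest = [g for g in universe if g not in members]
                n_rest = min(size - n_up, len(rest))
                if n_rest > 0:
                    members |= set(rng.choice(rest, n_rest, replace=False))
            else:
                members = set(rng.choice(universe, size, replace=False))
            if k == 0:
                members |= set(truth.inducible_list)
            catalog.add(level, term_id, f"synthetic term {term_id}", members)
    return catalog


def simulate_ppi(truth: SimTruth, config: SimConfig) -> PPINetwork:
    """Interaction graph: dense planted core plus Erdos-Renyi background.

    Core genes are wired pairwise with ``ppi_core_edge_prob`` (default 1:
    a complete subgraph, so each core node has within-core degree
    core_size - 1).  All other unordered pairs get an edge with
    ``ppi_background_edge_prob``.  Confidence scores are uniform on
    [400, 1000] so STRING-style medium-confidence thresholds retain all
    generated edges.
    """
    config.validate()
    rng = _rng(config, _SEED_OFFSET_PPI)
    universe = sorted(truth.planted_up | truth.planted_down | truth.null_genes)
    core = sorted(truth.planted_core)
    if len(core) < 2:
        raise ConfigError("planted core must have at least 2 genes")
    core_set = set(core)
    graph = nx.Graph()
    graph.add_nodes_from(universe)
    n = len(universe)
    # background edges via a single binomial draw over the pair index
    idx_u, idx_v = np.triu_indices(n, k=1)
    mask = rng.random(idx_u.size) < config.ppi_background_edge_prob
    for ui, vi in zip(idx_u[mask], idx_v[mask]):
        u, v = universe[ui], universe[vi]
        if u in core_set and v in core_set:
            continue
        graph.add_edge(u, v, score=float(rng.uniform(400, 1000)))
    for i, u in enumerate(core):
        for v in core[i + 1 :]:
            if rng.random() < config.ppi_core_edge_prob:
                graph.add_edge(u, v, score=float(rng.uniform(400, 1000)))
    return PPINetwork(graph=graph)


def simulate_inducible_list(truth: SimTruth) -> GeneList:
    """The planted literature-style inducible-gene list."""
    return GeneList.from_symbols(truth.inducible_list, source_label="synthetic")


def simulate_study(
    config: SimConfig,
) -> tuple[CountMatrix, AnnotationCatalog, PPINetwork, GeneList, SimTruth]:
    """Generate every input the pipeline consumes, sharing one truth."""
    matrix, truth = simulate_counts(config)
    catalog = simulate_annotations(truth, config)
    ppi = simulate_ppi(truth, config)
    inducible = simulate_inducible_list(truth)
    return matrix, catalog, ppi, inducible, truth


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["term_size_range"] = list(d["term_size_range"])
    return d
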