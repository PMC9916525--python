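"""Ortholog-mapped cross-species gene-set comparison.

Translates differential-expression gene lists between species through a
user-supplied ortholog table and tallies Venn regions for two to four
named sets.  When no table is given, mapping falls back to uppercase
symbol identity — an approximation that is logged as such.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import FormatError, InputError
from .io_formats import normalize_symbol

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrthologMap:
    """(source_symbol, target_species) -> target_symbol lookup."""

    table: pd.DataFrame  # columns: source_symbol, target_species, target_symbol

    def __post_init__(self) -> None:
        for col in ("source_symbol", "target_species", "target_symbol"):
            if col not in self.table.columns:
                raise FormatError(f"ortholog map missing column {col!r}")
        key = self.table[["source_symbol", "target_species"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise FormatError(
                f"duplicate ortholog entry for "
                f"({dup['source_symbol']}, {dup['target_species']})"
            )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "OrthologMap":
        frame = frame.copy()
        frame["source_symbol"] = frame["source_symbol"].map(normalize_symbol)
        frame["target_symbol"] = frame["target_symbol"].map(normalize_symbol)
        frame = frame.drop_duplicates(subset=["source_symbol", "target_species"])
        return cls(table=frame)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "OrthologMap":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str))

    def species(self) -> frozenset[str]:
        return frozenset(self.table["target_species"])


def map_symbols(
    genes: Iterable[str],
    ortholog_map: OrthologMap | None,
    species: str,
) -> tuple[frozenset[str], list[str], dict[str, list[str]]]:
    """Translate a gene set into ``species`` symbols.

    Returns ``(mapped, unmapped, collisions)`` where ``collisions`` maps
    each target symbol hit by more than one source gene to its sources.
    With no map, identity (uppercase) mapping is applied and logged as
    approximate.
    """
    genes = [normalize_symbol(g) for g in genes]
    if ortholog_map is None:
        logger.warning(
            "no ortholog map given; using uppercase symbol identity for %s "
            "(approximate)",
            species,
        )
        return frozenset(genes), [], {}
    if species not in ortholog_map.species():
        raise InputError(
            f"species {species!r} absent from ortholog map "
            f"(has {sorted(ortholog_map.species())})"
        )
    sub = ortholog_map.table[ortholog_map.table["target_species"] == species]
    lookup = dict(zip(sub["source_symbol"], sub["target_symbol"]))
    mapped: dict[str, list[str]] = {}
    unmapped: list[str] = []
    for g in genes:
        if g in lookup:
            mapped.setdefault(lookup[g], []).append(g)
        else:
            unmapped.append(g)
    collisions = {t: srcs for t, srcs in mapped.items() if len(srcs) > 1}
    for target, sources in collisions.items():
        logger.warning("many-to-one mapping: %s -> %s", sources, target)
    return frozenset(mapped), unmapped, collisions


def venn_counts(sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Venn region counts for 2-4 named gene sets.

    Each region is keyed by the membership pattern (e.g. ``A&B&~C``);
    region counts sum to the size of the overall union.  Pairwise
    intersection sizes are appended as ``pair:<X>&<Y>`` rows.
    """
    names = list(sets)
    if not 2 <= len(names) <= 4:
        raise InputError("venn_counts supports 2-4 sets")
    normalized = {
        name: frozenset(normalize_symbol(g) for g in members)
        for name, members in sets.items()
    }
    union = frozenset().union(*normalized.values())
    rows = []
    for pattern in itertools.product([True, False], repeat=len(names)):
        if not any(pattern):
            continue
        region = set(union)
        for name, inside in zip(names, pattern):
            region &= normalized[name] if inside else (union - normalized[name])
        label = "&".join(
            (name if inside else f"~{name}") for name, inside in zip(names, pattern)
        )
        rows.append({"region": label, "count": len(region)})
    for a, b in itertools.combinations(names, 2):
        rows.append(
            {
                "region": f"pair:{a}&{b}",
                "count": len(normalized[a] & normalized[b]),
            }
        )
    return pd.DataFrame(rows, columns=["region", "count"])
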