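"""Direction-aware gene-set over-representation testing.

Upper-tail hypergeometric test of a query gene list's overlap with each
annotated set, given a universe of testable genes, with Benjamini-Hochberg
correction across the sets tested within one (category, direction) family.
Gene-set collections are user-supplied GMT files; no pathway database is
bundled (database snapshots are version-dependent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy import stats

from .expression import bh_fdr

RESULT_COLUMNS = ("set_name", "overlap", "set_size", "query_size",
                  "universe_size", "p", "q")


class GmtError(ValueError):
    """Malformed GMT file."""


class EnrichmentError(ValueError):
    """Invalid enrichment input."""


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with the universe, dropping emptied sets."""
        universe = frozenset(universe)
        kept, dropped = {}, []
        for name, members in self.sets.items():
            restricted = members & universe
            if restricted:
                kept[name] = restricted
            else:
                dropped.append(name)
        if dropped:
            warnings.warn(f"dropped {len(dropped)} sets with no gene in the "
                          f"universe: {sorted(dropped)[:5]}...")
        return GeneSetCollection(kept, {k: self.descriptions.get(k, "")
                                        for k in kept})


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (per line: set name, description, member genes)."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as handle:
        lines = [line.rstrip("\n") for line in handle]
    if not any(line.strip() for line in lines):
        warnings.warn(f"empty GMT file: {path}")
        return GeneSetCollection({}, {})
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise GmtError(f"{path}:{lineno}: expected name, description and "
                           f"at least one member, got {len(fields)} fields")
        name, description = fields[0], fields[1]
        members = frozenset(g for g in fields[2:] if g)
        if not members:
            raise GmtError(f"{path}:{lineno}: set {name!r} has no members")
        sets[name] = members
        descriptions[name] = description
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as handle:
        for name in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[name]))
            handle.write(f"{name}\t{collection.descriptions.get(name, '')}\t{members}\n")


def hypergeom_enrich(query: Iterable[str], collection: GeneSetCollection,
                     universe: Iterable[str]) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` in each set.

    With N = |universe|, K = |set ∩ universe|, n = |query| and k the overlap,
    p = P(X >= k) for X ~ Hypergeometric(N, K, n). q-values are BH over all
    sets in the collection; rows come back sorted by q then p.
    """
    universe = frozenset(universe)
    query = frozenset(query)
    outside = query - universe
    if outside:
        raise EnrichmentError(f"query genes outside the universe: "
                              f"{sorted(outside)[:10]}")
    restricted = collection.restrict(universe)
    rows = []
    for name in sorted(restricted.sets):
        members = restricted.sets[name]
        k = len(query & members)
        # sf(k-1) = P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(members), len(query)))
        rows.append({"set_name": name, "overlap": k, "set_size": len(members),
                     "query_size": len(query), "universe_size": len(universe),
                     "p": min(p, 1.0)})
    result = pd.DataFrame(rows, columns=list(RESULT_COLUMNS[:-1]))
    result["q"] = bh_fdr(result["p"].to_numpy()) if len(result) else []
    return result.sort_values(["q", "p", "set_name"]).reset_index(drop=True)


def enrich_by_direction(assignments: pd.DataFrame, category: str,
                        collection: GeneSetCollection,
                        universe: Iterable[str] | None = None,
                        annotated_only: bool = False) -> dict[str, pd.DataFrame]:
    """Separate over-representation tables for a category's up and down genes.

    The default universe is every gene in ``assignments`` (the measured
    matrix); ``annotated_only`` restricts it to genes appearing in at least
    one set. BH correction is applied within each (category, direction)
    family separately. An empty query yields an empty table with a warning
    (the "no enrichment found" case).
    """
    if universe is None:
        universe = set(assignments["gene_id"])
    universe = frozenset(universe)
    if annotated_only:
        annotated = frozenset().union(*collection.sets.values()) if collection.sets \
            else frozenset()
        universe = universe & annotated
    out: dict[str, pd.DataFrame] = {}
    for direction in ("up", "down"):
        mask = (assignments["category"] == category) & \
               (assignments["direction"] == direction)
        query = frozenset(assignments.loc[mask, "gene_id"]) & universe
        if not query:
            warnings.warn(f"no {direction}-regulated category {category} genes "
                          f"in the universe; no enrichment computed")
            out[direction] = pd.DataFrame(columns=list(RESULT_COLUMNS))
            continue
        out[direction] = hypergeom_enrich(query, collection, universe)
    return out
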