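"""Cross-study comparison of directed differentially-expressed gene lists.

Given two studies' up/down gene lists (say chronic dietary restriction versus
acute starvation), quantify how significant their overlap is, how often
shared genes move in the same versus opposite directions, and how the
discordant genes distribute over the temporal-response categories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

DIRECTIONS = ("up", "down")


class ConcordanceError(ValueError):
    """Invalid directed gene list or cross-tab input."""


def _round_pct(numerator: int, denominator: int) -> int:
    """Percentage rounded to the nearest integer (half away from zero)."""
    return int(math.floor(100.0 * numerator / denominator + 0.5))


@dataclass
class DirectedGeneList:
    """Mapping gene id → direction (up/down) for one study."""

    directions: Mapping[str, str]
    label: str = ""

    def __post_init__(self) -> None:
        bad = {g: d for g, d in self.directions.items() if d not in DIRECTIONS}
        if bad:
            raise ConcordanceError(f"invalid directions: {bad}")
        self.directions = dict(self.directions)

    def __len__(self) -> int:
        return len(self.directions)

    def genes(self) -> frozenset[str]:
        return frozenset(self.directions)

    def n_up(self) -> int:
        return sum(1 for d in self.directions.values() if d == "up")

    def n_down(self) -> int:
        return sum(1 for d in self.directions.values() if d == "down")

    @classmethod
    def from_tsv(cls, path: str | Path, label: str = "") -> "DirectedGeneList":
        frame = pd.read_csv(path, sep="\t")
        for col in ("gene_id", "direction"):
            if col not in frame.columns:
                raise ConcordanceError(f"{path}: missing column {col!r}")
        dup = frame["gene_id"][frame["gene_id"].duplicated()].unique()
        if len(dup):
            raise ConcordanceError(f"{path}: duplicate genes {list(dup[:5])}")
        return cls(dict(zip(frame["gene_id"], frame["direction"])),
                   label=label or str(path))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"gene_id": list(self.directions),
                      "direction": list(self.directions.values())}
                     ).to_csv(path, sep="\t", index=False)


@dataclass
class ConcordanceSummary:
    """Direction agreement between two studies' shared genes."""

    n_shared: int
    n_same_direction: int
    n_opposite: int
    pct_same: int
    pct_opposite: int
    table: pd.DataFrame          # 2x2 counts, rows A up/down, cols B up/down
    shared: dict[str, tuple[str, str]] = field(default_factory=dict)
    label_a: str = "A"
    label_b: str = "B"


def overlap_test(list_a: DirectedGeneList, list_b: DirectedGeneList,
                 universe_size: int) -> tuple[int, float]:
    """Shared-gene count and upper-tail hypergeometric p for the overlap.

    p = P(X >= |A ∩ B|) for X ~ Hypergeometric(universe_size, |A|, |B|).
    """
    genes_a, genes_b = list_a.genes(), list_b.genes()
    union = genes_a | genes_b
    if universe_size < len(union):
        raise ConcordanceError(
            f"universe size {universe_size} smaller than the union ({len(union)})")
    k = len(genes_a & genes_b)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(genes_a), len(genes_b)))
    return k, min(p, 1.0)


def direction_concordance(list_a: DirectedGeneList,
                          list_b: DirectedGeneList) -> ConcordanceSummary:
    """Partition shared genes into same- and opposite-direction sets.

    Percentages are of the shared genes, rounded to the nearest integer.
    Genes present in only one list are excluded from the counts.
    """
    shared_genes = sorted(list_a.genes() & list_b.genes())
    shared = {g: (list_a.directions[g], list_b.directions[g]) for g in shared_genes}
    table = pd.DataFrame(0, index=[f"A_{d}" for d in DIRECTIONS],
                         columns=[f"B_{d}" for d in DIRECTIONS])
    for da, db in shared.values():
        table.loc[f"A_{da}", f"B_{db}"] += 1
    n_shared = len(shared)
    n_same = int(table.loc["A_up", "B_up"] + table.loc["A_down", "B_down"])
    n_opposite = n_shared - n_same
    pct_same = _round_pct(n_same, n_shared) if n_shared else 0
    pct_opposite = _round_pct(n_opposite, n_shared) if n_shared else 0
    return ConcordanceSummary(
        n_shared=n_shared, n_same_direction=n_same, n_opposite=n_opposite,
        pct_same=pct_same, pct_opposite=pct_opposite, table=table,
        shared=shared, label_a=list_a.label or "A", label_b=list_b.label or "B")


def updown_ratio(gene_list: DirectedGeneList) -> int:
    """Up- to down-regulated gene count ratio as a rounded percent."""
    n_down = gene_list.n_down()
    if n_down == 0:
        raise ConcordanceError("no down-regulated genes; up/down ratio undefined")
    return _round_pct(gene_list.n_up(), n_down)


def concordance_by_category(summary: ConcordanceSummary,
                            assignments: pd.DataFrame) -> pd.DataFrame:
    """Cross-tab of shared genes by (direction pattern x category).

    Returns a tidy DataFrame with columns ``pattern`` (e.g. ``A_up/B_down``),
    ``category``, ``count`` and ``row_pct`` (percent of that pattern's genes).
    Every shared gene must have a category assignment.
    """
    lookup = assignments.set_index("gene_id")["category"]
    missing = [g for g in summary.shared if g not in lookup.index]
    if missing:
        raise ConcordanceError(f"shared genes without a category assignment: "
                               f"{missing[:10]}")
    counts: dict[tuple[str, str], int] = {}
    for gene, (da, db) in summary.shared.items():
        key = (f"A_{da}/B_{db}", str(lookup[gene]))
        counts[key] = counts.get(key, 0) + 1
    pattern_totals: dict[str, int] = {}
    for (pattern, _), n in counts.items():
        pattern_totals[pattern] = pattern_totals.get(pattern, 0) + n
    rows = [{"pattern": pattern, "category": cat, "count": n,
             "row_pct": _round_pct(n, pattern_totals[pattern])}
            for (pattern, cat), n in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["pattern", "category", "count", "row_pct"])
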