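"""Hypergeometric over-representation analysis of a gene list.

Annotation-agnostic: gene sets enter only as a GMT-style mapping, the
universe is the set of genes actually measured in the analysis, and the
test is the upper tail of the hypergeometric distribution (probability of
seeing at least the observed overlap by chance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSet

__all__ = ["EnrichmentResult", "hypergeom_upper_tail", "enrich"]


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: int
    list_size: int
    set_size: int
    universe_size: int
    p_raw: float
    p_adj: float

    def __post_init__(self) -> None:
        if self.overlap > min(self.list_size, self.set_size):
            raise ValueError("overlap exceeds list or set size")
        if self.p_adj < self.p_raw - 1e-15:
            raise ValueError("adjusted p below raw p")


def hypergeom_upper_tail(overlap: int, list_size: int, set_size: int, universe_size: int) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(universe, set_size, list_size)."""
    if min(overlap, list_size, set_size, universe_size) < 0:
        raise ValueError("counts must be non-negative")
    if list_size > universe_size or set_size > universe_size:
        raise ValueError("list and set sizes cannot exceed the universe")
    if overlap > min(list_size, set_size):
        raise ValueError(
            f"overlap {overlap} exceeds min(list_size={list_size}, set_size={set_size})"
        )
    if overlap < max(0, list_size + set_size - universe_size):
        raise ValueError("overlap below the minimum forced by the counts")
    return float(min(1.0, stats.hypergeom.sf(overlap - 1, universe_size, set_size, list_size)))


def enrich(
    genes: Iterable[str],
    sets: Mapping[str, GeneSet],
    universe: Iterable[str],
    adjust: str = "benjamini_hochberg",
) -> list[EnrichmentResult]:
    """Test each gene set for over-representation of ``genes``.

    Genes and set members are intersected with the universe first; sets
    with no universe member are not tested.  Results sorted by raw p
    (ties by set name); adjustment over the tested sets only.
    """
    methods = {"benjamini_hochberg": "fdr_bh", "bonferroni": "bonferroni"}
    if adjust not in methods:
        raise ValueError(f"unknown adjustment {adjust!r}; choose from {sorted(methods)}")
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    glist = set(genes) & uni
    if not glist:
        raise ValueError("gene list does not intersect the universe")
    rows: list[tuple[str, int, int]] = []
    for name in sorted(sets):
        members = set(sets[name].members) & uni
        if not members:
            continue
        rows.append((name, len(glist & members), len(members)))
    if not rows:
        raise ValueError("no gene set intersects the universe")
    praw = [hypergeom_upper_tail(k, len(glist), m, len(uni)) for _, k, m in rows]
    padj = multipletests(praw, method=methods[adjust])[1]
    results = [
        EnrichmentResult(name, k, len(glist), m, len(uni), float(pr), float(min(1.0, pa)))
        for (name, k, m), pr, pa in zip(rows, praw, padj)
    ]
    results.sort(key=lambda r: (r.p_raw, r.set_name))
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "overlap": [r.overlap for r in results],
            "list_size": [r.list_size for r in results],
            "set_size": [r.set_size for r in results],
            "universe_size": [r.universe_size for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
        }
    )
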