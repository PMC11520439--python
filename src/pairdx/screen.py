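"""Differential gene-pair (DGP) screening.

For every candidate pair the +/-1 feature is cross-tabulated against the
case/control label and the resulting 2x2 table is tested with Fisher's
exact test (two-sided, minimum-likelihood convention).  Family-wise error
is controlled by Bonferroni over the pairs actually tested; the default
significance threshold on the adjusted p-value is 1e-20, reflecting the
very large effect sizes reversed pairs show in practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pairs import GenePair, PairFeatureMatrix

__all__ = [
    "ReversalTable",
    "ScreenResult",
    "reversal_table",
    "fisher_exact_two_sided",
    "bonferroni",
    "screen_pairs",
    "results_to_frame",
]

DEFAULT_ALPHA = 1e-20


@dataclass(frozen=True)
class ReversalTable:
    """Counts of +1 / -1 pair-feature states per group for one pair."""

    pair: GenePair
    n_case_pos: int
    n_case_neg: int
    n_ctrl_pos: int
    n_ctrl_neg: int

    def __post_init__(self) -> None:
        for n in (self.n_case_pos, self.n_case_neg, self.n_ctrl_pos, self.n_ctrl_neg):
            if n < 0:
                raise ValueError("reversal table counts must be non-negative")

    @property
    def as_2x2(self) -> list[list[int]]:
        return [[self.n_case_pos, self.n_case_neg], [self.n_ctrl_pos, self.n_ctrl_neg]]


@dataclass(frozen=True)
class ScreenResult:
    pair: GenePair
    table: ReversalTable
    p_raw: float
    p_adj: float
    direction: str  # case_enriched_pos | case_enriched_neg
    significant: bool


def _case_mask(features: PairFeatureMatrix, labels: pd.Series) -> np.ndarray:
    missing = [s for s in features.sample_ids if s not in labels.index]
    if missing:
        raise KeyError(f"sample {missing[0]!r} has no label")
    return labels.loc[list(features.sample_ids)].to_numpy() == 1


def reversal_table(features: PairFeatureMatrix, labels: pd.Series, pair: GenePair) -> ReversalTable:
    """Cross-tabulate one pair's +/-1 feature against the binary label."""
    case = _case_mask(features, labels)
    row = features.row(pair)
    pos = row == 1
    return ReversalTable(
        pair,
        int((pos & case).sum()),
        int((~pos & case).sum()),
        int((pos & ~case).sum()),
        int((~pos & ~case).sum()),
    )


def fisher_exact_two_sided(table: ReversalTable) -> float:
    """Two-sided Fisher exact p for a reversal table.

    Convention: the sum of hypergeometric probabilities, over all tables
    with the observed margins, that do not exceed the probability of the
    observed table.
    """
    p = stats.fisher_exact(table.as_2x2, alternative="two-sided").pvalue
    return float(min(p, 1.0))


def bonferroni(p_raw: float, n_tests: int) -> float:
    """Bonferroni family-wise adjustment: min(1, p * n_tests)."""
    if not 0.0 < p_raw <= 1.0:
        raise ValueError(f"p_raw must be in (0, 1], got {p_raw}")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p_raw * n_tests)


def screen_pairs(
    features: PairFeatureMatrix,
    labels: pd.Series,
    alpha_threshold: float = DEFAULT_ALPHA,
) -> list[ScreenResult]:
    """Test every pair in ``features``; Bonferroni over the tested pairs.

    Results are sorted by raw p ascending (ties broken by pair order);
    ``significant`` means adjusted p strictly below ``alpha_threshold``.
    """
    case = _case_mask(features, labels)
    n_case, n_ctrl = int(case.sum()), int((~case).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("screening requires at least one case and one control sample")
    pos = features.values == 1
    n_case_pos = pos[:, case].sum(axis=1)
    n_ctrl_pos = pos[:, ~case].sum(axis=1)
    n_tests = features.n_pairs
    results: list[ScreenResult] = []
    for i, pair in enumerate(features.pairs):
        tab = ReversalTable(
            pair,
            int(n_case_pos[i]),
            n_case - int(n_case_pos[i]),
            int(n_ctrl_pos[i]),
            n_ctrl - int(n_ctrl_pos[i]),
        )
        p_raw = fisher_exact_two_sided(tab)
        p_adj = bonferroni(p_raw, n_tests)
        direction = (
            "case_enriched_pos"
            if tab.n_case_pos * n_ctrl >= tab.n_ctrl_pos * n_case
            else "case_enriched_neg"
        )
        results.append(ScreenResult(pair, tab, p_raw, p_adj, direction, p_adj < alpha_threshold))
    results.sort(key=lambda r: (r.p_raw, r.pair))
    return results


def results_to_frame(results: Sequence[ScreenResult]) -> pd.DataFrame:
    """Tabular view of screen results (the on-disk TSV layout)."""
    return pd.DataFrame(
        {
            "gene_a": [r.pair.gene_a for r in results],
            "gene_b": [r.pair.gene_b for r in results],
            "n_case_pos": [r.table.n_case_pos for r in results],
            "n_case_neg": [r.table.n_case_neg for r in results],
            "n_ctrl_pos": [r.table.n_ctrl_pos for r in results],
            "n_ctrl_neg": [r.table.n_ctrl_neg for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
            "direction": [r.direction for r in results],
            "significant": [r.significant for r in results],
        }
    )
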