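"""Within-sample gene-pair features.

The central idea: replace absolute expression with the *sign* of the
within-sample difference between two genes.  For sample ``k`` and genes
``a``, ``b`` the pair feature is

    r_k = +1  if g_ak > g_bk
    r_k = -1  if g_ak <= g_bk  (exact ties map to -1)

Because r_k depends only on the ordering of two measurements taken in the
same sample, it is invariant to any strictly increasing per-sample
transformation (scaling, shifting, quantile normalisation, log choice) and
therefore robust to cross-cohort batch effects that act sample-wise.
Candidate pairs are restricted to genes sharing an annotated pathway, which
keeps the feature space tractable and biologically interpretable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet

__all__ = [
    "GenePair",
    "PairFeatureMatrix",
    "relative_expression",
    "candidate_pairs",
    "pair_feature_matrix",
    "concat_cohorts",
    "unrestricted_pair_count",
]


@dataclass(frozen=True, order=True)
class GenePair:
    """An unordered gene pair stored in canonical (lexicographic) order."""

    gene_a: str
    gene_b: str

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"gene pair must involve two distinct genes, got {self.gene_a!r} twice")
        if self.gene_a > self.gene_b:
            raise ValueError(
                f"gene pair ({self.gene_a!r}, {self.gene_b!r}) is not in canonical order; "
                "use GenePair.make()"
            )

    @classmethod
    def make(cls, g1: str, g2: str) -> "GenePair":
        """Build a pair from two gene ids in either order."""
        if g1 > g2:
            g1, g2 = g2, g1
        return cls(g1, g2)

    def __iter__(self):
        return iter((self.gene_a, self.gene_b))

    def __str__(self) -> str:  # used in error messages and TSV output
        return f"{self.gene_a}|{self.gene_b}"


@dataclass
class PairFeatureMatrix:
    """Matrix of +/-1 pair features, pairs on rows and samples on columns."""

    pairs: tuple[GenePair, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray  # int8, shape (n_pairs, n_samples), entries in {+1, -1}

    def __post_init__(self) -> None:
        self.pairs = tuple(self.pairs)
        self.sample_ids = tuple(self.sample_ids)
        self.values = np.asarray(self.values, dtype=np.int8)
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate pairs in PairFeatureMatrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in PairFeatureMatrix")
        if self.values.shape != (len(self.pairs), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.pairs)} pairs x {len(self.sample_ids)} samples"
            )
        if not np.isin(self.values, (-1, 1)).all():
            raise ValueError("pair feature values must be +1 or -1")
        self._index: dict[GenePair, int] = {p: i for i, p in enumerate(self.pairs)}

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, pair: GenePair) -> np.ndarray:
        try:
            return self.values[self._index[pair]]
        except KeyError:
            raise KeyError(f"pair {pair} not present in feature matrix") from None

    def subset(self, pairs: Sequence[GenePair]) -> "PairFeatureMatrix":
        """Rows restricted to ``pairs`` in the given order."""
        idx = [self._index[p] for p in pairs]
        return PairFeatureMatrix(tuple(pairs), self.sample_ids, self.values[idx])

    def select_samples(self, sample_ids: Sequence[str]) -> "PairFeatureMatrix":
        """Columns restricted to ``sample_ids`` in the given order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = [pos[s] for s in sample_ids]
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not present in feature matrix") from None
        return PairFeatureMatrix(self.pairs, tuple(sample_ids), self.values[:, idx])

    def design(self, pairs: Sequence[GenePair] | None = None) -> np.ndarray:
        """Samples-by-pairs float design matrix for model fitting."""
        mat = self if pairs is None else self.subset(pairs)
        return mat.values.T.astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=[str(p) for p in self.pairs], columns=list(self.sample_ids))


def relative_expression(g_a: float, g_b: float) -> int:
    """Sign indicator of the within-sample expression difference.

    Returns +1 when ``g_a > g_b`` and -1 otherwise (ties count as -1).
    """
    if not (math.isfinite(g_a) and math.isfinite(g_b)):
        raise ValueError(f"expression values must be finite, got ({g_a}, {g_b})")
    return 1 if g_a > g_b else -1


def candidate_pairs(sets: Mapping[str, GeneSet], matrix_genes: Iterable[str]) -> list[GenePair]:
    """All within-pathway pairs among measured genes, deduplicated.

    Each gene set is intersected with ``matrix_genes`` first; all unordered
    pairs of each intersection are pooled over sets and returned in
    lexicographic order, so the result does not depend on set iteration
    order.
    """
    measured = set(matrix_genes)
    out: set[GenePair] = set()
    for gs in sets.values():
        members = sorted(measured.intersection(gs.members))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                out.add(GenePair(members[i], members[j]))
    if not out:
        raise ValueError(
            "no gene set shares two or more genes with the expression matrix; "
            "check that gene identifiers in the GMT file match the matrix"
        )
    return sorted(out)


def pair_feature_matrix(expr: ExpressionMatrix, pairs: Sequence[GenePair]) -> PairFeatureMatrix:
    """Compute the +/-1 feature for every pair in every sample of one cohort."""
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    ia = np.empty(len(pairs), dtype=np.intp)
    ib = np.empty(len(pairs), dtype=np.intp)
    for k, p in enumerate(pairs):
        for gene, arr in ((p.gene_a, ia), (p.gene_b, ib)):
            if gene not in gene_pos:
                raise KeyError(
                    f"gene {gene!r} of pair {p} is not measured in cohort {expr.cohort_id!r}"
                )
            arr[k] = gene_pos[gene]
    vals = expr.values.to_numpy()
    feats = np.where(vals[ia] > vals[ib], 1, -1).astype(np.int8)
    return PairFeatureMatrix(tuple(pairs), tuple(expr.sample_ids), feats)


def concat_cohorts(
    cohorts: Sequence[tuple[ExpressionMatrix, pd.Series]],
    pairs: Sequence[GenePair],
) -> tuple[PairFeatureMatrix, pd.Series]:
    """Pool pair features across cohorts without mixing expression values.

    Features are computed independently within each cohort (so no numeric
    value is ever compared across cohorts) and the resulting columns are
    concatenated.  Sample ids are prefixed with ``<cohort_id>:`` to keep
    them globally unique; labels are re-keyed the same way.
    """
    blocks: list[np.ndarray] = []
    ids: list[str] = []
    labels_out: dict[str, int] = {}
    for expr, labels in cohorts:
        try:
            pfm = pair_feature_matrix(expr, pairs)
        except KeyError as exc:
            raise KeyError(f"{exc.args[0]} (while processing cohort {expr.cohort_id!r})") from None
        blocks.append(pfm.values)
        for sid in pfm.sample_ids:
            gid = f"{expr.cohort_id}:{sid}"
            if gid in labels_out:
                raise ValueError(f"sample id collision after cohort prefixing: {gid!r}")
            if sid not in labels.index:
                raise KeyError(f"sample {sid!r} of cohort {expr.cohort_id!r} has no label")
            labels_out[gid] = int(labels.loc[sid])
            ids.append(gid)
    features = PairFeatureMatrix(tuple(pairs), tuple(ids), np.hstack(blocks))
    lab = pd.Series(labels_out, name="label", dtype=np.int8)
    return features, lab.loc[list(ids)]


def unrestricted_pair_count(n_genes: int) -> int:
    """Number of unordered pairs among ``n_genes`` genes, n(n-1)/2.

    For the ~10k genes typically detected across platforms this exceeds
    fifty million, which is why candidate pairs are restricted to genes
    sharing a pathway.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be non-negative")
    return n_genes * (n_genes - 1) // 2
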