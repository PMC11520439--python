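"""Fitted model containers shared by the diagnostic and prognostic stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pairs import GenePair, PairFeatureMatrix

__all__ = ["DiagnosticModel", "PrognosticModel"]


def _check_sparse(pairs: tuple[GenePair, ...], coefficients: tuple[float, ...]) -> None:
    if len(pairs) != len(coefficients):
        raise ValueError("pairs and coefficients differ in length")
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate pairs in model")
    if any(c == 0.0 for c in coefficients):
        raise ValueError("zero-coefficient pairs must be pruned before constructing a model")


@dataclass(frozen=True)
class DiagnosticModel:
    """Sparse logistic model over +/-1 pair features.

    The decision score of sample ``k`` is ``intercept + sum_p w_p r_pk``;
    larger scores mean more case-like.
    """

    pairs: tuple[GenePair, ...]
    coefficients: tuple[float, ...]
    intercept: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_sparse(self.pairs, self.coefficients)

    def decision_function(self, features: PairFeatureMatrix) -> pd.Series:
        X = features.design(self.pairs)
        scores = X @ np.asarray(self.coefficients) + self.intercept
        return pd.Series(scores, index=list(features.sample_ids), name="score")

    def predict_proba(self, features: PairFeatureMatrix) -> pd.Series:
        s = self.decision_function(features)
        return pd.Series(1.0 / (1.0 + np.exp(-s.to_numpy())), index=s.index, name="probability")


@dataclass(frozen=True)
class PrognosticModel:
    """Sparse proportional-hazards model over +/-1 pair features.

    Defines the linear risk score ``s_k = sum_p beta_p r_pk`` (no baseline
    hazard term; only the ranking of scores is used downstream).
    """

    pairs: tuple[GenePair, ...]
    coefficients: tuple[float, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_sparse(self.pairs, self.coefficients)
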