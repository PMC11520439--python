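"""Stability-selected sparse classification on gene-pair features.

Feature selection repeats an 80/20 stratified split many times (default
100); each repeat fits an L1-penalized logistic regression on the train
part with the penalty chosen by internal cross-validation, and the pairs
receiving non-zero weight are counted — but only when that repeat's model
reaches a held-out AUC above the gate (default 0.8), so unstable splits
do not contribute.  Pairs selected in more than a threshold number of
repeats become candidates; the threshold itself can be tuned on a
disjoint evaluation set over a coarse grid.  The final model is a
10-fold-CV-tuned L1 logistic regression restricted to the candidates,
with zero-weight pairs pruned.  Random-forest and gradient-boosted-tree
baselines are provided for the method comparison only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .models import DiagnosticModel
from .pairs import GenePair, PairFeatureMatrix

__all__ = [
    "StabilityResult",
    "split_discovery",
    "stability_select",
    "select_candidates",
    "tune_occurrence_threshold",
    "fit_final_model",
    "fit_comparators",
    "comparison_report",
    "auc",
]

logger = logging.getLogger(__name__)

DEFAULT_CS = np.logspace(-2.0, 2.0, 9)


@dataclass(frozen=True)
class StabilityResult:
    """Per-pair selection counts over repeated random splits."""

    occurrence: dict  # GenePair -> int
    split_auc: tuple[float, ...]
    n_repeats: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.split_auc) != self.n_repeats:
            raise ValueError("one held-out AUC per repeat required")
        if any(v < 0 or v > self.n_repeats for v in self.occurrence.values()):
            raise ValueError("occurrence counts must lie in [0, n_repeats]")


def _substream_seed(seed: int, *key: int) -> int:
    """Deterministic child seed below 2**31 from a root seed and a key."""
    return int(np.random.SeedSequence(seed, spawn_key=key).generate_state(1)[0] % (2**31))


def split_discovery(
    labels: pd.Series,
    fraction_train: float = 0.8,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Stratified random split of labeled samples into train/test ids.

    The train part has exactly ``floor(fraction_train * n)`` samples,
    allocated to classes by largest remainder, with at least one sample
    of each class in both parts.
    """
    if not 0.0 < fraction_train < 1.0:
        raise ValueError("fraction_train must be in (0, 1)")
    counts = labels.value_counts()
    if len(counts) != 2 or (counts < 2).any():
        raise ValueError("each class needs at least 2 samples for a stratified split")
    n = len(labels)
    n_train = int(np.floor(fraction_train * n))
    classes = sorted(counts.index)
    quotas = {c: fraction_train * counts[c] for c in classes}
    alloc = {c: int(np.floor(quotas[c])) for c in classes}
    leftover = n_train - sum(alloc.values())
    for c in sorted(classes, key=lambda c: (-(quotas[c] - alloc[c]), c)):
        if leftover <= 0:
            break
        alloc[c] += 1
        leftover -= 1
    for c in classes:  # keep >=1 of each class on both sides
        alloc[c] = min(max(alloc[c], 1), counts[c] - 1)
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for c in classes:
        ids = [s for s in labels.index if labels[s] == c]
        perm = rng.permutation(len(ids))
        train.extend(ids[i] for i in perm[: alloc[c]])
        test.extend(ids[i] for i in perm[alloc[c]:])
    order = {s: i for i, s in enumerate(labels.index)}
    train.sort(key=order.__getitem__)
    test.sort(key=order.__getitem__)
    return train, test


def _l1_logistic(C: float, seed: int) -> LogisticRegression:
    return LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", random_state=seed, max_iter=2000
    )


def _fit_l1_logistic_cv(
    X: np.ndarray,
    y: np.ndarray,
    cv_folds: int,
    seed: int,
    Cs: Sequence[float] = DEFAULT_CS,
) -> tuple[LogisticRegression, float]:
    """L1 logistic fit with the penalty chosen by cross-validated AUC.

    The strength follows the one-standard-error rule: the strongest
    penalty (smallest C) whose mean CV AUC is within one standard error
    of the best, which keeps the selection sparse.
    """
    Cs = np.sort(np.asarray(Cs, dtype=float))
    skf = StratifiedKFold(cv_folds, shuffle=True, random_state=seed)
    scores = np.full((cv_folds, len(Cs)), np.nan)
    for f, (itr, ite) in enumerate(skf.split(X, y)):
        if len(np.unique(y[ite])) < 2 or len(np.unique(y[itr])) < 2:
            continue
        for j, C in enumerate(Cs):
            clf = _l1_logistic(C, seed).fit(X[itr], y[itr])
            scores[f, j] = roc_auc_score(y[ite], clf.decision_function(X[ite]))
    mean = np.nanmean(scores, axis=0)
    if np.isnan(mean).all():
        raise ValueError("cross-validation failed for every penalty value")
    j_best = int(np.nanargmax(mean))
    n_eff = np.sum(~np.isnan(scores[:, j_best]))
    se = float(np.nanstd(scores[:, j_best], ddof=1) / np.sqrt(n_eff)) if n_eff > 1 else 0.0
    j_sel = next(j for j in range(len(Cs)) if mean[j] >= mean[j_best] - se)
    C_sel = float(Cs[j_sel])
    return _l1_logistic(C_sel, seed).fit(X, y), C_sel


def stability_select(
    features: PairFeatureMatrix,
    labels: pd.Series,
    n_repeats: int = 100,
    fraction_train: float = 0.8,
    seed: int = 0,
    auc_gate: float = 0.8,
    cv_folds: int = 5,
) -> StabilityResult:
    """Count per-pair selection over repeated stratified splits.

    A pair's occurrence is incremented in a repeat only when (a) the
    repeat's L1 fit gives it a non-zero weight and (b) that repeat's
    model scores a held-out AUC above ``auc_gate``.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    lab = labels.loc[list(features.sample_ids)]
    occurrence: dict[GenePair, int] = {p: 0 for p in features.pairs}
    split_aucs: list[float] = []
    pos = {s: i for i, s in enumerate(features.sample_ids)}
    X_all = features.design()
    y_all = lab.to_numpy()
    for r in range(n_repeats):
        for attempt in range(10):
            rs = _substream_seed(seed, r, attempt)
            train_ids, test_ids = split_discovery(lab, fraction_train, seed=rs)
            itr = [pos[s] for s in train_ids]
            ite = [pos[s] for s in test_ids]
            if len(set(y_all[itr])) == 2 and len(set(y_all[ite])) == 2:
                break
            logger.warning("repeat %d: degenerate split, redrawing (attempt %d)", r, attempt + 1)
        clf, _ = _fit_l1_logistic_cv(X_all[itr], y_all[itr], cv_folds, rs)
        scores = clf.decision_function(X_all[ite])
        split_auc = auc(pd.Series(scores, index=test_ids), lab.loc[test_ids])
        split_aucs.append(split_auc)
        if split_auc > auc_gate:
            nz = np.flatnonzero(clf.coef_.ravel())
            for j in nz:
                occurrence[features.pairs[j]] += 1
    return StabilityResult(occurrence, tuple(split_aucs), n_repeats, seed)


def select_candidates(stab: StabilityResult, occurrence_threshold: int = 50) -> list[GenePair]:
    """Pairs selected in strictly more than ``occurrence_threshold`` repeats.

    Ordered by descending occurrence, ties broken lexicographically.
    """
    if not 1 <= occurrence_threshold <= stab.n_repeats:
        raise ValueError("occurrence_threshold must lie in [1, n_repeats]")
    chosen = [p for p, c in stab.occurrence.items() if c > occurrence_threshold]
    if not chosen:
        raise ValueError(
            f"no pair exceeds occurrence threshold {occurrence_threshold}; "
            "relax the threshold or increase n_repeats"
        )
    return sorted(chosen, key=lambda p: (-stab.occurrence[p], p))


def tune_occurrence_threshold(
    stab: StabilityResult,
    features_train: PairFeatureMatrix,
    labels_train: pd.Series,
    features_eval: PairFeatureMatrix,
    labels_eval: pd.Series,
    grid: Sequence[int] = tuple(range(10, 101, 10)),
    cv_folds: int = 10,
    seed: int = 0,
) -> int:
    """Pick the occurrence threshold whose final model scores best on the
    evaluation set; ties resolve to the smaller threshold."""
    best: tuple[float, int] | None = None
    for t in sorted(grid):
        try:
            cands = select_candidates(stab, t)
            model = fit_final_model(features_train, labels_train, cands, cv_folds, seed)
        except ValueError:
            continue
        a = auc(model.decision_function(features_eval), labels_eval.loc[list(features_eval.sample_ids)])
        if best is None or a > best[0]:
            best = (a, t)
    if best is None:
        raise ValueError("every grid threshold produced an empty candidate set or degenerate model")
    return best[1]


def fit_final_model(
    features: PairFeatureMatrix,
    labels: pd.Series,
    pairs: Sequence[GenePair],
    cv_folds: int = 10,
    seed: int = 0,
) -> DiagnosticModel:
    """L1 logistic regression on the candidate pairs, penalty by k-fold CV.

    Zero-coefficient pairs are pruned from the returned model.
    """
    lab = labels.loc[list(features.sample_ids)]
    counts = lab.value_counts()
    if len(counts) != 2 or (counts < cv_folds).any():
        raise ValueError(f"final fit needs at least cv_folds={cv_folds} samples per class")
    sub = features.subset(list(pairs))
    clf, C_sel = _fit_l1_logistic_cv(sub.design(), lab.to_numpy(), cv_folds, seed)
    coef = clf.coef_.ravel()
    nz = np.flatnonzero(coef)
    if nz.size == 0:
        raise ValueError("all coefficients are zero at the selected penalty; no model retained")
    kept = tuple(sub.pairs[i] for i in nz)
    meta = {"seed": seed, "penalty": C_sel, "cv_folds": cv_folds}
    intercept = float(np.atleast_1d(clf.intercept_)[0])
    return DiagnosticModel(kept, tuple(float(c) for c in coef[nz]), intercept, meta)


def fit_comparators(
    features: PairFeatureMatrix,
    labels: pd.Series,
    pairs: Sequence[GenePair],
    seed: int = 0,
) -> dict:
    """Fixed-seed tree-ensemble baselines on the same +/-1 features."""
    from xgboost import XGBClassifier

    X = features.subset(list(pairs)).design()
    y = labels.loc[list(features.sample_ids)].to_numpy()
    rf = RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1)
    xgb = XGBClassifier(
        n_estimators=300,
        max_depth=3,
        learning_rate=0.1,
        random_state=seed,
        n_jobs=1,
        eval_metric="logloss",
    )
    rf.fit(X, y)
    xgb.fit(X, y)
    return {"random_forest": rf, "gradient_boosted_trees": xgb}


def comparison_report(
    model: DiagnosticModel,
    comparators: Mapping[str, object],
    eval_sets: Mapping[str, tuple[PairFeatureMatrix, pd.Series]],
    comparator_pairs: Sequence[GenePair] | None = None,
) -> pd.DataFrame:
    """One AUC per method per evaluation set (lasso_logistic + baselines).

    ``comparator_pairs`` must match the pairs the comparators were fit on
    (defaults to the sparse model's own pairs).
    """
    if comparator_pairs is None:
        comparator_pairs = model.pairs
    rows = []
    for name, (feats, labs) in eval_sets.items():
        labs = labs.loc[list(feats.sample_ids)]
        rows.append({"eval_set": name, "method": "lasso_logistic",
                     "auc": auc(model.decision_function(feats), labs)})
        X = feats.subset(list(comparator_pairs)).design()
        for mname, m in comparators.items():
            scores = pd.Series(m.predict_proba(X)[:, 1], index=list(feats.sample_ids))
            rows.append({"eval_set": name, "method": mname, "auc": auc(scores, labs)})
    return pd.DataFrame(rows)


def auc(scores: pd.Series, labels: pd.Series) -> float:
    """Area under the ROC curve (Mann-Whitney form, ties count 1/2)."""
    labels = labels.loc[scores.index]
    if labels.nunique() != 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels.to_numpy(), scores.to_numpy()))
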