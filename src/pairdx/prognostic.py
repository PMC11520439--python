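"""Pair-based survival modelling.

Pipeline: each candidate pair's +/-1 feature is tested in a univariate
Cox proportional-hazards model (Wald p < 0.05 filter, unadjusted), the
survivors enter an L1-penalized multivariable Cox fit whose penalty is
chosen by cross-validated partial likelihood, and the resulting linear
risk score stratifies patients at the median into high/low-risk groups
compared by Kaplan-Meier curves and the log-rank test.  Discrimination
at fixed horizons uses the cumulative-cases/dynamic-controls AUC with
inverse-probability-of-censoring weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .models import PrognosticModel
from .pairs import GenePair, PairFeatureMatrix

__all__ = [
    "StratifiedCohort",
    "univariate_cox",
    "filter_univariate",
    "lasso_cox",
    "risk_score",
    "median_split",
    "km_logrank",
    "time_dependent_auc",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StratifiedCohort:
    """Median-split risk stratification of one cohort."""

    scores: pd.Series
    group: pd.Series  # 'high' | 'low' per sample
    cutoff: float

    def __post_init__(self) -> None:
        high = self.group == "high"
        if (self.scores[high] < self.cutoff).any():
            raise ValueError("high-risk group contains scores below the cutoff")
        if (self.scores[~high] >= self.cutoff).any():
            raise ValueError("low-risk group contains scores at or above the cutoff")


def _align(feature: pd.Series, survival: pd.DataFrame) -> pd.DataFrame:
    common = [s for s in feature.index if s in survival.index]
    if not common:
        raise ValueError("no overlap between feature samples and survival table")
    return pd.DataFrame(
        {
            "x": feature.loc[common].astype(float),
            "time": survival.loc[common, "time"].astype(float),
            "event": survival.loc[common, "event"].astype(int),
        }
    )


def univariate_cox(feature: pd.Series, survival: pd.DataFrame) -> tuple[float, float, float]:
    """Single-covariate Cox PH fit; returns (beta, hazard ratio, Wald p)."""
    df = _align(feature, survival)
    if df["event"].sum() < 2:
        raise ValueError("univariate Cox requires at least 2 events")
    if df["x"].nunique() < 2:
        raise ValueError("feature is constant; hazard ratio not identifiable")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    beta = float(cph.params_["x"])
    return beta, float(np.exp(beta)), float(cph.summary.loc["x", "p"])


def filter_univariate(
    pairs: Sequence[GenePair],
    features: PairFeatureMatrix,
    survival: pd.DataFrame,
    alpha: float = 0.05,
) -> list[GenePair]:
    """Pairs with univariate Cox Wald p < alpha, ordered by p ascending.

    Degenerate pairs (constant feature, too few events) are skipped with
    a log entry rather than failing the whole filter.
    """
    pvals: list[tuple[float, GenePair]] = []
    for p in pairs:
        feat = pd.Series(features.row(p), index=list(features.sample_ids))
        try:
            _, _, pv = univariate_cox(feat, survival)
        except Exception as exc:  # lifelines convergence errors included
            logger.warning("pair %s skipped in univariate Cox filter: %s", p, exc)
            continue
        if pv < alpha:
            pvals.append((pv, p))
    if not pvals:
        raise ValueError(f"no pair passes the univariate Cox filter at p < {alpha}")
    pvals.sort(key=lambda t: (t[0], t[1]))
    return [p for _, p in pvals]


def _breslow_loglik(X: np.ndarray, time: np.ndarray, event: np.ndarray, beta: np.ndarray) -> float:
    """Breslow partial log-likelihood of a fixed coefficient vector."""
    order = np.argsort(-time, kind="stable")  # descending time
    eta = X[order] @ beta
    t_sorted = time[order]
    e_sorted = event[order]
    # log cumulative sum of exp(eta) over the risk set {j: t_j >= t_i}
    m = float(eta.max())
    log_risk = m + np.log(np.cumsum(np.exp(eta - m)))
    # with ties at t_i the risk set includes all samples with equal time
    ll = 0.0
    i = 0
    n = len(t_sorted)
    while i < n:
        j = i
        while j + 1 < n and t_sorted[j + 1] == t_sorted[i]:
            j += 1
        lr = log_risk[j]  # risk set at this time: indices 0..j
        for k in range(i, j + 1):
            if e_sorted[k]:
                ll += eta[k] - lr
        i = j + 1
    return float(ll)


def lasso_cox(
    features: PairFeatureMatrix,
    survival: pd.DataFrame,
    pairs: Sequence[GenePair],
    cv_folds: int = 10,
    seed: int = 0,
) -> PrognosticModel:
    """L1-penalized Cox fit over ``pairs``; penalty by cross-validated
    partial likelihood (Verweij & van Houwelingen), zero coefficients
    pruned."""
    sub = features.subset(list(pairs))
    common = [s for s in sub.sample_ids if s in survival.index]
    if len(common) < len(sub.sample_ids):
        missing = next(s for s in sub.sample_ids if s not in survival.index)
        raise KeyError(f"sample {missing!r} has no survival record")
    X = sub.design()
    time = survival.loc[common, "time"].to_numpy(float)
    event = survival.loc[common, "event"].to_numpy(int)
    if event.sum() < cv_folds:
        raise ValueError(f"lasso_cox requires at least cv_folds={cv_folds} events")
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, alpha_min_ratio=0.01, n_alphas=50, max_iter=100000)
    path.fit(X, y)
    alphas = np.asarray(path.alphas_)

    contrib = np.full((cv_folds, len(alphas)), np.nan)
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for f, (itr, _) in enumerate(kf.split(X)):
        fold = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=list(alphas), max_iter=100000)
        fold.fit(X[itr], Surv.from_arrays(event=event[itr].astype(bool), time=time[itr]))
        fold_alphas = list(fold.alphas_)
        for i, a in enumerate(alphas):
            if a not in fold_alphas:
                continue
            beta = fold.coef_[:, fold_alphas.index(a)]
            contrib[f, i] = _breslow_loglik(X, time, event, beta) - _breslow_loglik(
                X[itr], time[itr], event[itr], beta
            )
    valid = ~np.isnan(contrib).any(axis=0)
    if not valid.any():
        raise ValueError("cross-validation failed for every penalty value")
    cvpl = np.where(valid, np.nansum(contrib, axis=0), -np.inf)
    # one-standard-error rule: the sparsest (largest) penalty whose CV
    # partial likelihood is within one fold-SE of the best
    i_best = int(np.argmax(cvpl))
    se = float(np.std(contrib[:, i_best], ddof=1) * np.sqrt(cv_folds))
    best = next(i for i in range(len(alphas)) if cvpl[i] >= cvpl[i_best] - se)
    final = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[float(alphas[best])], max_iter=100000)
    final.fit(X, y)
    coef = final.coef_.ravel()
    nz = np.flatnonzero(coef)
    if nz.size == 0:
        raise ValueError("all Cox coefficients are zero at the selected penalty")
    meta = {"alpha": float(alphas[best]), "seed": seed, "cv_folds": cv_folds}
    return PrognosticModel(
        tuple(sub.pairs[i] for i in nz), tuple(float(c) for c in coef[nz]), meta
    )


def risk_score(model: PrognosticModel, features: PairFeatureMatrix) -> pd.Series:
    """Linear risk score s_k = sum_p beta_p * r_pk per sample."""
    X = features.design(model.pairs)
    return pd.Series(X @ np.asarray(model.coefficients), index=list(features.sample_ids), name="risk_score")


def median_split(scores: pd.Series) -> StratifiedCohort:
    """Split at the median score; scores >= median are 'high' risk."""
    if len(scores) < 2:
        raise ValueError("median split requires at least 2 samples")
    cutoff = float(scores.median())
    group = pd.Series(np.where(scores >= cutoff, "high", "low"), index=scores.index, name="group")
    return StratifiedCohort(scores, group, cutoff)


def km_logrank(
    strata: StratifiedCohort,
    survival: pd.DataFrame,
) -> tuple[dict[str, pd.DataFrame], float]:
    """Kaplan-Meier curves per risk group plus the two-group log-rank p.

    Each curve is a table (time, at_risk, events, survival) including the
    time-zero row.
    """
    groups = sorted(strata.group.unique())
    if len(groups) < 2:
        raise ValueError("both risk groups must be non-empty for a log-rank comparison")
    curves: dict[str, pd.DataFrame] = {}
    parts: dict[str, pd.DataFrame] = {}
    for g in groups:
        ids = [s for s in strata.group.index if strata.group[s] == g and s in survival.index]
        if not ids:
            raise ValueError(f"risk group {g!r} has no survival records")
        sub = survival.loc[ids]
        parts[g] = sub
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=g)
        et = kmf.event_table
        curves[g] = pd.DataFrame(
            {
                "time": et.index.to_numpy(float),
                "at_risk": et["at_risk"].to_numpy(int),
                "events": et["observed"].to_numpy(int),
                "survival": kmf.survival_function_[g].to_numpy(float),
            }
        )
    res = logrank_test(
        parts[groups[0]]["time"], parts[groups[1]]["time"],
        event_observed_A=parts[groups[0]]["event"],
        event_observed_B=parts[groups[1]]["event"],
    )
    return curves, float(res.p_value)


def _censoring_survival(time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """KM estimate of the censoring distribution G(t) = P(C > t).

    Returns (timeline, values) of the right-continuous step function; the
    left limit G(t-) is the value at the last timeline point strictly
    below t.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(time, 1 - event)
    timeline = kmf.survival_function_.index.to_numpy(float)
    values = kmf.survival_function_.iloc[:, 0].to_numpy(float)
    return timeline, values


def _step_eval(timeline: np.ndarray, values: np.ndarray, t: np.ndarray, left: bool) -> np.ndarray:
    side = "left" if left else "right"
    idx = np.searchsorted(timeline, t, side=side) - 1
    out = np.ones_like(np.asarray(t, dtype=float))
    mask = idx >= 0
    out[mask] = values[idx[mask]]
    return out


def time_dependent_auc(scores: pd.Series, survival: pd.DataFrame, horizon: float) -> float:
    """Cumulative/dynamic AUC at ``horizon`` with IPC weighting.

    Cases are subjects with an observed event at or before the horizon,
    controls those still event-free beyond it; subjects censored before
    the horizon contribute only through the censoring-distribution
    weights.  With zero censoring this reduces exactly to the plain
    Mann-Whitney AUC on the dichotomized outcome.
    """
    common = [s for s in scores.index if s in survival.index]
    s = scores.loc[common].to_numpy(float)
    time = survival.loc[common, "time"].to_numpy(float)
    event = survival.loc[common, "event"].to_numpy(int)
    case = (time <= horizon) & (event == 1)
    ctrl = time > horizon
    if not case.any() or not ctrl.any():
        raise ValueError(
            f"horizon {horizon}: needs at least one event by the horizon and one "
            "subject still at risk beyond it"
        )
    timeline, values = _censoring_survival(time, event)
    g_case = _step_eval(timeline, values, time[case], left=True)
    g_ctrl = _step_eval(timeline, values, np.full(ctrl.sum(), float(horizon)), left=False)
    if (g_case <= 0).any() or (g_ctrl <= 0).any():
        raise ValueError(f"horizon {horizon}: censoring survival reaches zero; weights undefined")
    w_case = 1.0 / g_case
    w_ctrl = 1.0 / g_ctrl
    sc = s[case][:, None]
    st = s[ctrl][None, :]
    conc = (sc > st).astype(float) + 0.5 * (sc == st)
    w = w_case[:, None] * w_ctrl[None, :]
    return float((w * conc).sum() / w.sum())
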