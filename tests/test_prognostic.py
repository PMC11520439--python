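"""Univariate Cox filtering, L1 Cox selection, stratification and
time-dependent discrimination."""

import numpy as np
import pandas as pd
import pytest

from pairdx.diagnostic import auc as plain_auc
from pairdx.models import PrognosticModel
from pairdx.pairs import GenePair, concat_cohorts
from pairdx.prognostic import (
    filter_univariate,
    km_logrank,
    lasso_cox,
    median_split,
    risk_score,
    time_dependent_auc,
    univariate_cox,
)
from pairdx.simulate import PlantedPair, SurvivalConfig, SyntheticConfig, generate_study


def survival_study(seed, betas, n_pairs=None, cases=500, censor=40.0):
    """Cases-only study whose pair features vary freely (rates 0.5/0.5)."""
    n_pairs = n_pairs if n_pairs is not None else len(betas)
    planted = tuple(
        PlantedPair(f"G{2 * i - 1:04d}", f"G{2 * i:04d}", 0.5, 0.5)
        for i in range(1, n_pairs + 1)
    )
    cfg = SyntheticConfig(
        n_cohorts=1, cases_per_cohort=cases, controls_per_cohort=2,
        n_genes=2 * n_pairs if (2 * n_pairs) % 2 == 0 else 2 * n_pairs + 1,
        n_pathways=1, genes_per_pathway=2 * n_pairs,
        planted_pairs=planted, batch_shift_sd=0.0,
        survival=SurvivalConfig(baseline_rate=0.1, betas=betas, censor_time_max=censor),
        seed=seed,
    )
    study = generate_study(cfg)
    pairs = [pp.pair for pp in planted]
    feats, _ = concat_cohorts(study.cohorts, pairs)
    surv = study.survival
    feats = feats.select_samples([s for s in feats.sample_ids if s in surv.index])
    return feats, surv, pairs


def feature_series(feats, pair):
    return pd.Series(feats.row(pair), index=list(feats.sample_ids), dtype=float)


class TestUnivariateCox:
    def test_recovers_planted_effect(self):
        feats, surv, pairs = survival_study(1, (("G0001", "G0002", 1.0),), n_pairs=1)
        beta, hr, p = univariate_cox(feature_series(feats, pairs[0]), surv)
        assert 0.7 <= beta <= 1.3
        assert hr == pytest.approx(np.exp(beta))
        assert p < 1e-6

    def test_null_effect_mostly_insignificant(self):
        hits = 0
        for seed in range(50):
            feats, surv, pairs = survival_study(100 + seed, (), n_pairs=1, cases=500)
            beta, _, p = univariate_cox(feature_series(feats, pairs[0]), surv)
            if abs(beta) < 0.25 and p > 0.05:
                hits += 1
        assert hits >= 45  # >= 90% of runs

    def test_sign_flip_negates_beta(self):
        feats, surv, pairs = survival_study(2, (("G0001", "G0002", 1.0),), n_pairs=1)
        f = feature_series(feats, pairs[0])
        b1, _, _ = univariate_cox(f, surv)
        b2, _, _ = univariate_cox(-f, surv)
        assert b2 == pytest.approx(-b1, rel=1e-6)

    def test_constant_feature_rejected(self):
        feats, surv, pairs = survival_study(3, (), n_pairs=1)
        const = pd.Series(1.0, index=list(feats.sample_ids))
        with pytest.raises(ValueError, match="constant"):
            univariate_cox(const, surv)


class TestFilterUnivariate:
    def test_planted_retained_nulls_mostly_dropped(self):
        betas = tuple((f"G{2 * i - 1:04d}", f"G{2 * i:04d}", 1.2 if i % 2 else -1.2)
                      for i in range(1, 4))
        feats, surv, pairs = survival_study(4, betas, n_pairs=13)
        kept = filter_univariate(pairs, feats, surv)
        planted = {GenePair.make(a, b) for a, b, _ in betas}
        assert planted <= set(kept)
        assert len(set(kept) - planted) <= 2

    def test_alpha_one_keeps_everything_nondegenerate(self):
        feats, surv, pairs = survival_study(5, (), n_pairs=4)
        assert set(filter_univariate(pairs, feats, surv, alpha=1.0)) == set(pairs)

    def test_ordering_by_p_deterministic(self):
        betas = (("G0001", "G0002", 1.0),)
        feats, surv, pairs = survival_study(6, betas, n_pairs=5)
        k1 = filter_univariate(pairs, feats, surv, alpha=1.0)
        k2 = filter_univariate(pairs, feats, surv, alpha=1.0)
        assert k1 == k2
        assert k1[0] == GenePair("G0001", "G0002")  # smallest p first


class TestLassoCox:
    def test_two_planted_eight_null_support_recovery(self):
        betas = (("G0001", "G0002", 1.0), ("G0003", "G0004", -1.0))
        feats, surv, pairs = survival_study(7, betas, n_pairs=10, cases=400)
        model = lasso_cox(feats, surv, pairs, seed=7)
        truth = {GenePair.make(a, b): v for a, b, v in betas}
        coef = dict(zip(model.pairs, model.coefficients))
        for p, b in truth.items():
            assert p in coef and np.sign(coef[p]) == np.sign(b)
        assert len(set(model.pairs) - set(truth)) <= 2
        assert len(model.pairs) <= len(pairs)

    def test_seeded_determinism(self):
        betas = (("G0001", "G0002", 1.0),)
        feats, surv, pairs = survival_study(8, betas, n_pairs=4)
        assert lasso_cox(feats, surv, pairs, seed=3) == lasso_cox(feats, surv, pairs, seed=3)

    def test_too_few_events_rejected(self):
        feats, surv, pairs = survival_study(9, (), n_pairs=2, cases=20)
        few = surv.iloc[:8]
        with pytest.raises((ValueError, KeyError)):
            lasso_cox(feats.select_samples(list(few.index)), few, pairs, cv_folds=10)


class TestRiskScore:
    def test_single_pair_value(self):
        model = PrognosticModel((GenePair("G0001", "G0002"),), (0.5,))
        feats, _, _ = survival_study(10, (), n_pairs=1, cases=4)
        scores = risk_score(model, feats)
        expected = 0.5 * feats.row(GenePair("G0001", "G0002")).astype(float)
        assert np.array_equal(scores.to_numpy(), expected)

    def test_matches_dot_product_oracle_and_linearity(self, rng):
        feats, _, pairs = survival_study(11, (), n_pairs=5, cases=30)
        coefs = tuple(rng.normal(size=len(pairs)))
        model = PrognosticModel(tuple(pairs), coefs)
        scores = risk_score(model, feats)
        oracle = feats.design(pairs) @ np.asarray(coefs)
        assert np.allclose(scores.to_numpy(), oracle)
        negated = PrognosticModel(tuple(pairs), tuple(-c for c in coefs))
        assert np.allclose(risk_score(negated, feats).to_numpy(), -scores.to_numpy())

    def test_missing_pair_is_error(self):
        model = PrognosticModel((GenePair("GX", "GY"),), (1.0,))
        feats, _, _ = survival_study(12, (), n_pairs=1, cases=4)
        with pytest.raises(KeyError):
            risk_score(model, feats)


class TestMedianSplit:
    def test_even_odd_and_tied_scores(self):
        ten = pd.Series(np.arange(10.0), index=[f"s{i}" for i in range(10)])
        strat = median_split(ten)
        assert (strat.group == "high").sum() == 5

        odd = pd.Series(np.arange(7.0), index=[f"s{i}" for i in range(7)])
        assert (median_split(odd).group == "high").sum() == 4  # (n+1)/2

        flat = pd.Series(1.0, index=[f"s{i}" for i in range(4)])
        assert (median_split(flat).group == "high").all()

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            median_split(pd.Series([1.0], index=["s"]))


class TestKmLogrank:
    def _strata(self, n_high, n_low):
        idx = [f"h{i}" for i in range(n_high)] + [f"l{i}" for i in range(n_low)]
        scores = pd.Series([1.0] * n_high + [0.0] * n_low, index=idx)
        return median_split(scores), idx

    def test_identical_groups_give_p_one(self):
        strata, idx = self._strata(4, 4)
        times = [2.0, 4.0, 6.0, 8.0] * 2
        events = [1, 0, 1, 1] * 2
        surv = pd.DataFrame({"time": times, "event": events}, index=idx)
        curves, p = km_logrank(strata, surv)
        assert p == pytest.approx(1.0)

    def test_km_product_limit_hand_computed(self):
        # times (2,4,4,7,9,12), events (1,1,0,1,0,0):
        # S(2)=5/6, S(4)=5/6*4/5=2/3, S(7)=2/3*2/3=4/9
        strata, idx = self._strata(6, 2)
        surv = pd.DataFrame(
            {"time": [2, 4, 4, 7, 9, 12, 5, 6], "event": [1, 1, 0, 1, 0, 0, 1, 0]},
            index=idx,
        )
        curves, _ = km_logrank(strata, surv)
        high = curves["high"].set_index("time")
        assert high.loc[7.0, "survival"] == pytest.approx(4 / 9)
        s = curves["high"]["survival"].to_numpy()
        assert s[0] == 1.0 and (np.diff(s) <= 1e-12).all()

    def test_strong_effect_significant(self):
        betas = tuple((f"G{2 * i - 1:04d}", f"G{2 * i:04d}", 1.0 if i % 2 else -1.0)
                      for i in range(1, 4))
        feats, surv, pairs = survival_study(13, betas, n_pairs=3, cases=200)
        model = lasso_cox(feats, surv, pairs, seed=13)
        strata = median_split(risk_score(model, feats))
        _, p = km_logrank(strata, surv)
        assert p < 0.05


class TestTimeDependentAuc:
    def test_perfect_ranking_no_censoring(self):
        idx = [f"s{i}" for i in range(10)]
        times = np.arange(1.0, 11.0)
        surv = pd.DataFrame({"time": times, "event": 1}, index=idx)
        scores = pd.Series(-times, index=idx)  # earliest deaths get highest risk
        for h in (2.5, 5.0, 8.5):
            assert time_dependent_auc(scores, surv, h) == 1.0

    def test_random_scores_near_half(self, rng):
        feats, surv, _ = survival_study(14, (), n_pairs=2, cases=400)
        scores = pd.Series(rng.normal(size=len(surv)), index=list(surv.index))
        h = float(np.median(surv["time"]))
        assert abs(time_dependent_auc(scores, surv, h) - 0.5) <= 0.1

    def test_equals_plain_auc_without_censoring(self):
        betas = (("G0001", "G0002", 1.0), ("G0003", "G0004", -1.0))
        feats, surv, pairs = survival_study(15, betas, n_pairs=4, cases=300, censor=None)
        assert (surv["event"] == 1).all()
        model = lasso_cox(feats, surv, pairs, seed=15)
        scores = risk_score(model, feats)
        for q in (0.25, 0.5, 0.75):
            h = float(surv["time"].quantile(q))
            labels = pd.Series((surv["time"] <= h).astype(int), index=surv.index)
            assert time_dependent_auc(scores, surv, h) == pytest.approx(
                plain_auc(scores, labels), abs=1e-10
            )

    def test_invalid_horizon_names_horizon(self):
        idx = ["a", "b"]
        surv = pd.DataFrame({"time": [5.0, 6.0], "event": [1, 1]}, index=idx)
        scores = pd.Series([1.0, 0.0], index=idx)
        with pytest.raises(ValueError, match="99"):
            time_dependent_auc(scores, surv, 99.0)
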