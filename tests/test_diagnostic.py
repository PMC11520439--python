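"""Stability selection, threshold tuning and the sparse diagnostic model."""

import numpy as np
import pandas as pd
import pytest

from pairdx.diagnostic import (
    StabilityResult,
    auc,
    comparison_report,
    fit_comparators,
    fit_final_model,
    select_candidates,
    split_discovery,
    stability_select,
    tune_occurrence_threshold,
)
from pairdx.pairs import GenePair, candidate_pairs, concat_cohorts
from pairdx.simulate import PlantedPair, SyntheticConfig, generate_study

P1, P2, P3 = GenePair("GA", "GB"), GenePair("GC", "GD"), GenePair("GE", "GF")


def study_features(seed, planted, n_genes=44, cases=100, controls=100, pathways=2):
    cfg = SyntheticConfig(
        n_cohorts=1, cases_per_cohort=cases, controls_per_cohort=controls,
        n_genes=n_genes, n_pathways=pathways, genes_per_pathway=n_genes // pathways,
        planted_pairs=planted, batch_shift_sd=0.0, seed=seed,
    )
    study = generate_study(cfg)
    return study, study.cohorts[0]


class TestSplitDiscovery:
    def test_published_discovery_split_sizes(self):
        # 474 discovery samples (372 cases, 102 controls) at 80/20
        labels = pd.Series([1] * 372 + [0] * 102,
                           index=[f"s{i}" for i in range(474)])
        train, test = split_discovery(labels, 0.8, seed=0)
        assert (len(train), len(test)) == (379, 95)

    def test_partition_and_stratification(self):
        labels = pd.Series([1] * 30 + [0] * 14, index=[f"s{i}" for i in range(44)])
        train, test = split_discovery(labels, 0.8, seed=4)
        assert sorted(train + test) == sorted(labels.index)
        assert not set(train) & set(test)
        for part in (train, test):
            assert labels.loc[part].nunique() == 2

    def test_deterministic_given_seed(self):
        labels = pd.Series([1] * 20 + [0] * 20, index=[f"s{i}" for i in range(40)])
        assert split_discovery(labels, seed=9) == split_discovery(labels, seed=9)
        assert split_discovery(labels, seed=9) != split_discovery(labels, seed=10)

    def test_tiny_class_rejected(self):
        labels = pd.Series([1, 0, 0, 0], index=list("abcd"))
        with pytest.raises(ValueError, match="at least 2"):
            split_discovery(labels)


class TestAuc:
    def test_reference_values(self):
        idx = list("abcd")
        labels = pd.Series([1, 0, 1, 0], index=idx)
        assert auc(pd.Series([0.9, 0.8, 0.3, 0.2], index=idx), labels) == 0.75
        assert auc(pd.Series([0.9, 0.1, 0.8, 0.2], index=idx), labels) == 1.0
        assert auc(pd.Series([0.5] * 4, index=idx), labels) == 0.5

    def test_invariant_under_monotone_transform(self, rng):
        idx = [f"s{i}" for i in range(50)]
        scores = pd.Series(rng.normal(size=50), index=idx)
        labels = pd.Series(rng.choice([0, 1], size=50), index=idx)
        labels.iloc[:2] = [0, 1]
        base = auc(scores, labels)
        assert auc(np.exp(scores * 3 + 1), labels) == pytest.approx(base)

    def test_single_class_rejected(self):
        idx = list("ab")
        with pytest.raises(ValueError, match="both classes"):
            auc(pd.Series([0.1, 0.2], index=idx), pd.Series([1, 1], index=idx))


class TestStabilitySelect:
    @pytest.fixture(scope="class")
    def planted_run(self):
        """1 strongly reversed pair + 20 null pairs on 200 samples."""
        study, (expr, labels) = study_features(
            7, (PlantedPair("G0001", "G0002", 0.95, 0.05),), n_genes=42, pathways=1
        )
        planted = GenePair("G0001", "G0002")
        nulls = [GenePair(f"G{i:04d}", f"G{i + 1:04d}") for i in range(3, 42, 2)]
        feats, lab = concat_cohorts([(expr, labels)], [planted] + nulls)
        stab = stability_select(feats, lab, n_repeats=100, seed=7)
        return planted, nulls, feats, lab, stab

    def test_planted_occurrence_dominates_nulls(self, planted_run):
        planted, nulls, _, _, stab = planted_run
        max_null = max(stab.occurrence[p] for p in nulls)
        assert stab.occurrence[planted] >= 90
        assert max_null <= 25
        assert stab.occurrence[planted] - max_null >= 50  # wide selection margin

    def test_one_auc_per_repeat(self, planted_run):
        *_, stab = planted_run
        assert len(stab.split_auc) == stab.n_repeats == 100

    def test_deterministic_given_seed(self, planted_run):
        planted, nulls, feats, lab, stab = planted_run
        again = stability_select(feats, lab, n_repeats=10, seed=3)
        twice = stability_select(feats, lab, n_repeats=10, seed=3)
        assert again == twice

    def test_zero_repeats_rejected(self, planted_run):
        _, _, feats, lab, _ = planted_run
        with pytest.raises(ValueError):
            stability_select(feats, lab, n_repeats=0)


class TestSelectCandidates:
    def _stab(self, occ):
        return StabilityResult(occ, tuple([0.9] * 100), 100, 0)

    def test_strictly_greater_than_threshold(self):
        stab = self._stab({P1: 73, P2: 50, P3: 12})
        assert select_candidates(stab, 50) == [P1]

    def test_boundary_threshold_equals_n_repeats(self):
        stab = self._stab({P1: 100, P2: 99})
        with pytest.raises(ValueError):
            select_candidates(stab, 100)

    def test_order_independent_of_dict_order(self):
        occ = {P1: 60, P2: 80, P3: 60}
        rev = dict(reversed(list(occ.items())))
        assert select_candidates(self._stab(occ), 50) == select_candidates(self._stab(rev), 50)
        assert select_candidates(self._stab(occ), 50) == [P2, P1, P3]  # ties lexicographic


class TestTuneThreshold:
    @pytest.fixture(scope="class")
    def tuning_setup(self):
        study, (expr, labels) = study_features(
            5,
            (PlantedPair("G0001", "G0002", 0.9, 0.1), PlantedPair("G0003", "G0004", 0.9, 0.1)),
            n_genes=44, cases=150, controls=150, pathways=2,
        )
        informative = [GenePair("G0001", "G0002"), GenePair("G0003", "G0004")]
        nulls = [GenePair(f"G{i:04d}", f"G{i + 1:04d}") for i in range(5, 20, 2)]
        feats, lab = concat_cohorts([(expr, labels)], informative + nulls)
        disc, ev = split_discovery(lab, seed=5)
        occ = {p: 75 for p in informative}
        occ.update({p: 15 for p in nulls})
        stab = StabilityResult(occ, tuple([0.95] * 100), 100, 5)
        return (feats.select_samples(disc), lab.loc[disc],
                feats.select_samples(ev), lab.loc[ev], stab, informative)

    def test_chosen_threshold_recovers_informative_pairs(self, tuning_setup):
        fd, ld, fe, le, stab, informative = tuning_setup
        t = tune_occurrence_threshold(stab, fd, ld, fe, le, seed=5)
        assert t in range(10, 101, 10)
        model = fit_final_model(fd, ld, select_candidates(stab, t), seed=5)
        assert set(informative) <= set(model.pairs)
        assert auc(model.decision_function(fe), le) >= 0.95

    def test_single_value_grid(self, tuning_setup):
        fd, ld, fe, le, stab, _ = tuning_setup
        assert tune_occurrence_threshold(stab, fd, ld, fe, le, grid=[30], seed=5) == 30

    def test_all_grid_values_empty_is_error(self, tuning_setup):
        fd, ld, fe, le, _, _ = tuning_setup
        empty = StabilityResult({P1: 0}, tuple([0.5] * 100), 100, 0)
        with pytest.raises(ValueError, match="grid"):
            tune_occurrence_threshold(empty, fd, ld, fe, le)


class TestFinalModel:
    @pytest.fixture(scope="class")
    def three_pair_study(self):
        planted = (
            PlantedPair("G0001", "G0002", 0.9, 0.1),
            PlantedPair("G0003", "G0004", 0.9, 0.1),
            PlantedPair("G0023", "G0024", 0.1, 0.9),
        )
        study, (expr, labels) = study_features(6, planted, n_genes=44, cases=150, controls=150)
        ppairs = [pp.pair for pp in planted]
        nulls = [GenePair("G0005", "G0006"), GenePair("G0007", "G0008")]
        feats, lab = concat_cohorts([(expr, labels)], ppairs + nulls)
        return planted, feats, lab

    def test_recovers_planted_pairs_with_correct_signs(self, three_pair_study):
        planted, feats, lab = three_pair_study
        model = fit_final_model(feats, lab, list(feats.pairs), seed=1)
        coef = dict(zip(model.pairs, model.coefficients))
        for pp in planted:
            assert pp.pair in coef
            expected_sign = 1.0 if pp.rate_case > pp.rate_control else -1.0
            assert np.sign(coef[pp.pair]) == expected_sign

    def test_null_labels_give_no_informative_model(self, three_pair_study, rng):
        _, feats, lab = three_pair_study
        permuted = pd.Series(rng.permutation(lab.to_numpy()), index=lab.index)
        try:
            model = fit_final_model(feats, permuted, list(feats.pairs), seed=1)
        except ValueError:
            return  # everything pruned: acceptable null outcome
        scores = model.decision_function(feats)
        assert abs(auc(scores, permuted) - 0.5) < 0.2

    def test_refit_same_seed_identical(self, three_pair_study):
        _, feats, lab = three_pair_study
        m1 = fit_final_model(feats, lab, list(feats.pairs), seed=2)
        m2 = fit_final_model(feats, lab, list(feats.pairs), seed=2)
        assert m1 == m2


class TestComparators:
    def test_all_methods_strong_on_easy_study(self, three_pair_setup=None):
        planted = (
            PlantedPair("G0001", "G0002", 0.95, 0.05),
            PlantedPair("G0003", "G0004", 0.95, 0.05),
        )
        study, (expr, labels) = study_features(8, planted, n_genes=44, cases=150, controls=150)
        feats, lab = concat_cohorts([(expr, labels)], [pp.pair for pp in planted])
        disc, ev = split_discovery(lab, seed=8)
        fd, ld = feats.select_samples(disc), lab.loc[disc]
        fe, le = feats.select_samples(ev), lab.loc[ev]
        model = fit_final_model(fd, ld, list(feats.pairs), seed=8)
        comp = fit_comparators(fd, ld, list(feats.pairs), seed=8)
        report = comparison_report(model, comp, {"eval": (fe, le)},
                                   comparator_pairs=list(feats.pairs))
        assert set(report["method"]) == {"lasso_logistic", "random_forest",
                                         "gradient_boosted_trees"}
        assert len(report) == 3  # one AUC per method per evaluation set
        assert (report["auc"] >= 0.9).all()

        report2 = comparison_report(model, fit_comparators(fd, ld, list(feats.pairs), seed=8),
                                    {"eval": (fe, le)}, comparator_pairs=list(feats.pairs))
        assert report.equals(report2)  # seeded determinism
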