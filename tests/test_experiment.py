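import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from conftest import labels_from_array, random_expression
from interlink.datasets import ExpressionDataset, LabelVector
from interlink.errors import ConfigurationError, UndefinedAUCError
from interlink.experiment import (
    ExperimentConfig,
    auc_diff,
    compare_gr_methods,
    compute_auc,
    run_damage_experiment,
    run_fold,
    ttest_select,
    wilcoxon_compare,
)
from interlink.synthetic_data import SyntheticCohort, SyntheticConfig, generate_cohort


def brute_force_auc(scores, truth):
    """Independent oracle: pairwise concordance count with half-credit ties."""
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == -1]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def enumerate_wilcoxon_p(diffs):
    """Independent oracle: exact two-sided p over all 2^n sign assignments."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total_w = []
    for signs in itertools.product([0, 1], repeat=n):
        total_w.append(sum(r for r, s in zip(ranks, signs) if s))
    total_w = np.asarray(total_w)
    p_low = np.mean(total_w <= w_obs + 1e-9)
    p_high = np.mean(total_w >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_low, p_high))


class TestTtestSelect:
    def test_shifted_feature_beats_noise(self, rng):
        n = 40
        y = np.array([1] * 20 + [-1] * 20)
        values = np.column_stack([
            np.where(y == 1, 3.0, 0.0) + rng.normal(0, 1, n),  # shifted
            rng.normal(0, 1, n),  # noise
        ])
        data = ExpressionDataset(values, tuple(f"P{i}" for i in range(n)), ("shifted", "noise"))
        out = ttest_select(data, labels_from_array(y), n_select=1)
        assert out.feature_ids == ("shifted",)

    def test_constant_feature_ranked_last(self, rng):
        n = 20
        y = np.array([1] * 10 + [-1] * 10)
        values = np.column_stack([np.full(n, 5.0), rng.normal(0, 1, n)])
        data = ExpressionDataset(values, tuple(f"P{i}" for i in range(n)), ("const", "noise"))
        out = ttest_select(data, labels_from_array(y), n_select=1)
        assert out.feature_ids == ("noise",)

    def test_select_all_preserves_order(self, rng):
        data = random_expression(rng, 10, 6)
        y = labels_from_array([1, -1] * 5)
        out = ttest_select(data, y, n_select=6)
        assert out.feature_ids == data.feature_ids
        assert np.array_equal(out.values, data.values)

    def test_uses_only_labeled_patients(self, rng):
        # feature 0 separates classes only among labeled patients
        n = 30
        y = np.array([1] * 10 + [-1] * 10 + [0] * 10)
        f0 = np.concatenate([np.full(10, 4.0), np.full(10, 0.0), rng.normal(0, 1, 10)])
        values = np.column_stack([f0 + rng.normal(0, 0.5, n), rng.normal(0, 1, n)])
        data = ExpressionDataset(values, tuple(f"P{i}" for i in range(n)), ("a", "b"))
        out = ttest_select(data, labels_from_array(y), n_select=1)
        assert out.feature_ids == ("a",)

    def test_too_few_labeled_per_class(self, rng):
        data = random_expression(rng, 5, 3)
        with pytest.raises(ConfigurationError):
            ttest_select(data, labels_from_array([1, -1, 0, 0, 0]), n_select=1)


class TestComputeAuc:
    def test_perfect_ranking(self):
        assert compute_auc([3.0, 2.0, 1.0], [1, 1, -1]) == 1.0

    def test_all_ties_give_half(self):
        assert compute_auc([1.0] * 6, [1, -1, 1, -1, 1, -1]) == 0.5

    def test_printed_toy_case(self):
        assert compute_auc([0.9, 0.8, 0.3, 0.1], [1, -1, 1, -1]) == pytest.approx(0.75)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            truth = rng.choice([-1, 1], size=n)
            if np.abs(truth.sum()) == n:
                truth[0] *= -1
            scores = np.round(rng.normal(size=n), 1)  # rounding creates ties
            assert compute_auc(scores, truth) == pytest.approx(
                brute_force_auc(scores, truth), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedAUCError):
            compute_auc([0.1, 0.2], [1, 1])


class TestWilcoxonCompare:
    def test_uniform_shift_gives_minimal_statistic(self):
        a = np.linspace(0.5, 0.8, 15)
        b = a + 0.1
        stat, p = wilcoxon_compare(a, b)
        assert stat == 0.0
        assert p == pytest.approx(2 * 0.5**15, rel=1e-9)

    def test_identical_vectors_degenerate(self):
        a = np.linspace(0, 1, 8)
        with pytest.raises(ConfigurationError):
            wilcoxon_compare(a, a)

    def test_antisymmetric_in_arguments(self, rng):
        a = rng.normal(size=12)
        b = a + rng.normal(size=12)
        assert wilcoxon_compare(a, b)[1] == pytest.approx(wilcoxon_compare(b, a)[1])

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_exact_p_matches_sign_enumeration(self, n, rng):
        for trial in range(5):
            d = np.round(rng.normal(size=n), 1)
            d[d == 0] = 0.05
            # zero baseline keeps the paired differences exactly equal to d
            stat, p = wilcoxon_compare(np.zeros(n), d)
            assert p == pytest.approx(enumerate_wilcoxon_p(d), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        d = rng.normal(size=14)
        a = rng.normal(size=14)
        stat, p = wilcoxon_compare(a, a + d)
        ref = scipy_wilcoxon(a + d, a, alternative="two-sided", method="exact")
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_large_n_normal_approximation(self, rng):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        d = rng.normal(0.2, 1.0, size=40)
        d[d == 0] = 0.1
        a = rng.normal(size=40)
        _, p = wilcoxon_compare(a, a + d)
        ref = scipy_wilcoxon(a + d, a, alternative="two-sided", method="approx", correction=True)
        assert p == pytest.approx(ref.pvalue, rel=0.05)


FAST = ExperimentConfig(damage_fractions=(0.0, 0.9), n_repeats=1, seed=3)


class TestDamageExperiment:
    def test_determinism(self, small_cohort):
        a = run_damage_experiment(small_cohort, FAST)
        b = run_damage_experiment(small_cohort, FAST)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_zero_damage_equals_original(self, small_cohort):
        result = run_damage_experiment(small_cohort, FAST)
        sub = result.records[result.records["damage_fraction"] == 0.0]
        go = sub[sub["graph_kind"] == "GO"].sort_values(["repeat", "fold"])["auc"]
        gd = sub[sub["graph_kind"] == "GD"].sort_values(["repeat", "fold"])["auc"]
        assert np.array_equal(go.to_numpy(), gd.to_numpy())

    def test_record_count_and_auc_range(self, small_cohort):
        cfg = ExperimentConfig(damage_fractions=(0.0, 0.5), n_repeats=2, seed=1)
        result = run_damage_experiment(small_cohort, cfg)
        assert len(result.records) == 4 * 2 * 2 * 5  # kinds x fractions x repeats x folds
        assert result.records["auc"].between(0, 1).all()

    def test_augmentation_beats_damage_at_high_damage(self, small_cohort):
        cfg = ExperimentConfig(damage_fractions=(0.9,), n_repeats=3, seed=7)
        result = run_damage_experiment(small_cohort, cfg)
        summary = result.summaries.set_index("graph_kind")["auc_mean"]
        assert summary["GA"] > summary["GD"]

    def test_unlabeled_cohort_rejected(self, small_cohort):
        masked = SyntheticCohort(
            small_cohort.gene_expr,
            small_cohort.mirna_expr,
            small_cohort.targets,
            LabelVector(
                np.where(np.arange(82) < 40, small_cohort.labels.values, 0),
                small_cohort.labels.patient_ids,
            ),
            truth={},
        )
        with pytest.raises(ConfigurationError):
            run_damage_experiment(masked, FAST)


class TestNoLeakage:
    def test_signal_only_in_test_folds_scores_at_chance(self):
        """Plant class signal exclusively in held-out patients: if feature
        selection, graph fitting and coefficient fitting only ever see
        training labels, the test AUC must stay at chance level.

        Balanced classes are used because with imbalanced labels the global
        score mean is nonzero and test-fold clustering then shifts scores
        through node degrees alone — a transductive pathway that involves no
        label information but still moves AUC off 0.5.
        """
        from sklearn.model_selection import StratifiedKFold

        aucs = []
        for seed in range(4):
            cohort = generate_cohort(SyntheticConfig(seed=seed, class_balance=0.5))
            cfg = ExperimentConfig(damage_fractions=(0.0,), seed=seed)
            info_g = [cohort.gene_expr.feature_ids.index(g)
                      for g in cohort.truth["informative_genes"]]
            info_m = [cohort.mirna_expr.feature_ids.index(m)
                      for m in cohort.truth["informative_mirnas"]]
            skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
            noise = np.random.default_rng(seed + 1000)
            for train_idx, test_idx in skf.split(np.zeros(82), cohort.labels.values):
                # erase the planted signal for training patients only
                gene_values = cohort.gene_expr.values.copy()
                mirna_values = cohort.mirna_expr.values.copy()
                gene_values[np.ix_(train_idx, info_g)] = noise.normal(
                    size=(len(train_idx), len(info_g))
                )
                mirna_values[np.ix_(train_idx, info_m)] = noise.normal(
                    size=(len(train_idx), len(info_m))
                )
                doctored = SyntheticCohort(
                    ExpressionDataset(gene_values, cohort.gene_expr.patient_ids,
                                      cohort.gene_expr.feature_ids),
                    ExpressionDataset(mirna_values, cohort.mirna_expr.patient_ids,
                                      cohort.mirna_expr.feature_ids),
                    cohort.targets,
                    cohort.labels,
                    truth={},
                )
                train_mask = np.zeros(82, dtype=bool)
                train_mask[train_idx] = True
                scores = run_fold(doctored, train_mask, cfg, fold_seed=seed)
                aucs.append(
                    compute_auc(scores["GA@0"][test_idx], cohort.labels.values[test_idx])
                )
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_permuting_test_labels_leaves_scores_unchanged(self, small_cohort):
        cfg = ExperimentConfig(damage_fractions=(0.5,), seed=2)
        train_mask = np.zeros(82, dtype=bool)
        train_mask[:60] = True
        base = run_fold(small_cohort, train_mask, cfg, fold_seed=1)
        permuted_labels = small_cohort.labels.values.copy()
        permuted_labels[60:] = -permuted_labels[60:]
        permuted = SyntheticCohort(
            small_cohort.gene_expr,
            small_cohort.mirna_expr,
            small_cohort.targets,
            LabelVector(permuted_labels, small_cohort.labels.patient_ids),
            truth={},
        )
        other = run_fold(permuted, train_mask, cfg, fold_seed=1)
        for key in base:
            assert np.array_equal(base[key], other[key])


class TestAucDiff:
    def test_planted_feature_tops_table(self):
        cohort = generate_cohort(
            SyntheticConfig(n_patients=60, n_genes=30, n_mirnas=10, n_target_pairs=5,
                            n_informative_pairs=1, effect_size=2.5, seed=4)
        )
        cfg = ExperimentConfig(n_repeats=1, seed=4)
        informative = cohort.truth["informative_genes"][0]
        noise = [f for f in cohort.gene_expr.feature_ids if f != informative][:5]
        table = auc_diff(cohort, cfg, [informative] + noise)
        assert table.iloc[0]["feature"] == informative

    def test_duplicated_feature_loses_importance(self):
        """A redundant copy of the informative feature keeps the information
        when either copy is removed, so its leave-one-out importance drops
        far below the importance the unique copy commands on its own (it is
        not exactly zero: removing a copy still reweights the Euclidean
        distances behind the graph)."""
        cohort = generate_cohort(
            SyntheticConfig(n_patients=60, n_genes=30, n_mirnas=10, n_target_pairs=5,
                            n_informative_pairs=1, effect_size=2.5, seed=9)
        )
        informative = cohort.truth["informative_genes"][0]
        gi = cohort.gene_expr.feature_ids.index(informative)
        values = np.column_stack([cohort.gene_expr.values, cohort.gene_expr.values[:, gi]])
        dup = ExpressionDataset(
            values, cohort.gene_expr.patient_ids,
            cohort.gene_expr.feature_ids + ("dup",),
        )
        cohort2 = SyntheticCohort(dup, cohort.mirna_expr, cohort.targets, cohort.labels, {})
        cfg = ExperimentConfig(n_repeats=2, seed=9)
        noise = [f for f in cohort.gene_expr.feature_ids if f != informative][:6]
        with_dup = auc_diff(cohort2, cfg, [informative, "dup"] + noise)
        without_dup = auc_diff(cohort, cfg, [informative] + noise)
        dup_importance = with_dup.set_index("feature").loc["dup", "auc_diff"]
        solo_importance = without_dup.set_index("feature").loc[informative, "auc_diff"]
        assert abs(dup_importance) < 0.1
        assert solo_importance > 3 * abs(dup_importance)

    def test_row_count_matches_features(self, small_cohort):
        cfg = ExperimentConfig(n_repeats=1, seed=1)
        features = list(small_cohort.gene_expr.feature_ids[:4])
        table = auc_diff(small_cohort, cfg, features)
        assert len(table) == 4
        assert list(table["auc_diff"]) == sorted(table["auc_diff"], reverse=True)


class TestCompareGrMethods:
    def test_table_layout_and_sanity(self, small_cohort):
        cfg = ExperimentConfig(n_repeats=1, seed=5)
        comparison = compare_gr_methods(small_cohort, cfg)
        assert list(comparison.methods["method"]) == ["GR1", "GR2", "GR3", "GR4", "GR5"]
        assert comparison.methods[["auc_gr", "auc_ga"]].stack().between(0, 1).all()
        assert 0 <= comparison.auc_go <= 1
        assert 0 <= comparison.auc_mirna <= 1

    def test_augmented_at_least_chance_with_planted_signal(self, small_cohort):
        cfg = ExperimentConfig(n_repeats=1, seed=5)
        comparison = compare_gr_methods(small_cohort, cfg)
        assert (comparison.methods["auc_ga"] >= 0.5).all()
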