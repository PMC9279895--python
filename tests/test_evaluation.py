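"""Evaluation: simplex grid, metrics, screening, LOOCV protocols, baselines."""

import itertools
import math

import numpy as np
import pytest

from mkfusion import (
    CohortSpec,
    ConfusionMatrix,
    KernelWeights,
    baseline_harness,
    confusion_metrics,
    default_kernel_specs,
    feature_screen,
    generate_cohort,
    loocv_fixed_weights,
    nested_weight_search,
    roc_auc,
    simplex_grid,
)


class TestSimplexGrid:
    def test_coarsest_grid_is_the_vertices(self):
        grid = simplex_grid(3, step=1.0)
        assert set(grid.points) == {(0, 0, 1), (0, 1, 0), (1, 0, 0)}

    def test_half_step_enumeration(self):
        grid = simplex_grid(3, step=0.5)
        assert len(grid) == 6
        assert all(abs(sum(p) - 1) < 1e-12 for p in grid)

    def test_study_resolution_grid_size(self):
        assert len(simplex_grid(3, step=0.05)) == 231

    @pytest.mark.parametrize("M", [2, 3, 4])
    @pytest.mark.parametrize("k", [1, 3, 7, 20, 40])
    def test_size_matches_closed_form(self, M, k):
        grid = simplex_grid(M, step=1.0 / k)
        assert len(grid) == math.comb(k + M - 1, M - 1)
        assert len(set(grid.points)) == len(grid)  # duplicate-free

    def test_lexicographic_order_and_validity(self):
        grid = simplex_grid(3, step=0.25)
        assert list(grid.points) == sorted(grid.points)
        for p in grid:
            KernelWeights(p)  # all points satisfy the simplex invariants

    def test_non_divisor_step_rejected(self):
        with pytest.raises(ValueError, match="step"):
            simplex_grid(3, step=0.3)


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            # the two worked example panels of the study's prediction rule
            ((25, 3, 5, 19), (84.6, 89.3, 79.2)),
            ((22, 6, 4, 20), (80.8, 78.6, 83.3)),
            ((10, 0, 0, 10), (100.0, 100.0, 100.0)),
        ],
    )
    def test_worked_examples(self, counts, expected):
        tp, fn, fp, tn = counts
        cm = ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)
        assert confusion_metrics(cm) == expected

    def test_empty_class_is_an_explicit_error(self):
        with pytest.raises(ValueError, match="undefined"):
            confusion_metrics(ConfusionMatrix(tp=0, fn=0, fp=2, tn=3))

    def test_from_predictions(self):
        y = np.array([1, 1, 1, -1, -1])
        yhat = np.array([1, -1, 1, -1, 1])
        cm = ConfusionMatrix.from_predictions(y, yhat)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (2, 1, 1, 1)


def mann_whitney_auc(y, s):
    """Pair-enumeration oracle: P(score_case > score_control) + ties/2."""
    pos = [si for yi, si in zip(y, s) if yi > 0]
    neg = [si for yi, si in zip(y, s) if yi < 0]
    wins = sum((p > q) + 0.5 * (p == q) for p, q in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([1, 1, -1, -1], [3.0, 2.0, 1.0, 0.0])
        assert auc == 1.0

    def test_constant_scores_give_half(self):
        _, auc = roc_auc([1, -1, 1, -1], [0.5, 0.5, 0.5, 0.5])
        assert auc == 0.5

    def test_three_of_four_concordant_pairs(self):
        _, auc = roc_auc([1, 1, -1, -1], [0.9, 0.4, 0.6, 0.2])
        assert auc == 0.75

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_pair_enumeration_with_ties(self, rng, trial):
        n = 12
        y = np.concatenate([np.ones(6), -np.ones(6)])
        s = rng.choice([0.0, 0.25, 0.5, 1.0, 2.0], size=n)  # forced ties
        _, auc = roc_auc(y, s)
        assert auc == pytest.approx(mann_whitney_auc(y, s), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        y = np.concatenate([np.ones(8), -np.ones(8)])
        s = rng.standard_normal(16)
        _, auc1 = roc_auc(y, s)
        _, auc2 = roc_auc(y, np.exp(3.0 * s) + 7.0)
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            roc_auc([1, 1], [0.1, 0.2])


class TestFeatureScreen:
    def test_identical_groups_t_zero_p_one(self, tiny_cohort):
        import pandas as pd
        from mkfusion import MultimodalDataset

        block = pd.DataFrame(
            np.tile([[1.0, 2.0], [3.0, 1.0]], (2, 1)),
            index=["a", "b", "c", "d"],
        )
        ds = MultimodalDataset(
            subject_ids=("a", "b", "c", "d"),
            y=np.array([1.0, 1.0, -1.0, -1.0]),
            blocks={"m": block},
        )
        screen = feature_screen(ds)
        np.testing.assert_allclose(screen["t"], 0.0, atol=1e-12)
        np.testing.assert_allclose(screen["p"], 1.0, atol=1e-12)

    def test_welch_t_hand_example(self):
        """Groups (1,2,3) vs (4,5,6): Welch t = -3/sqrt(2/3) = -3.674."""
        import pandas as pd
        from mkfusion import MultimodalDataset

        ds = MultimodalDataset(
            subject_ids=tuple("abcdef"),
            y=np.array([1.0] * 3 + [-1.0] * 3),
            blocks={"m": pd.DataFrame({"f": [1.0, 2, 3, 4, 5, 6]},
                                      index=list("abcdef"))},
        )
        t = feature_screen(ds)["t"].iloc[0]
        assert t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-3)

    def test_bonferroni_threshold_per_modality(self, default_cohort):
        screen = feature_screen(default_cohort)
        eeg = screen[screen.modality == "eeg"]
        assert eeg["bonferroni_alpha"].iloc[0] == pytest.approx(0.05 / 266, rel=1e-12)
        assert eeg["bonferroni_alpha"].nunique() == 1

    def test_default_cohort_signal_pattern(self, default_cohort):
        """Clinical features carry most of the detectable signal."""
        screen = feature_screen(default_cohort)
        frac_sig = screen.groupby("modality")["significant_bonferroni"].mean()
        assert frac_sig["clinical"] > frac_sig["eeg"]
        assert frac_sig["clinical"] > frac_sig["pet"]
        assert frac_sig["clinical"] >= 0.5


class TestLoocvFixedWeights:
    def test_exactly_n_predictions(self, tiny_cohort):
        res = loocv_fixed_weights(tiny_cohort, weights=(0.6, 0.2, 0.2))
        assert len(res.scores) == tiny_cohort.n
        assert len(res.y_pred) == tiny_cohort.n

    def test_vertex_weights_equal_single_modality_loocv(self, tiny_cohort):
        """beta at a vertex reproduces the one-kernel LOOCV exactly."""
        specs = default_kernel_specs(tiny_cohort)
        vertex = loocv_fixed_weights(tiny_cohort, specs, weights=(1.0, 0.0, 0.0))
        single_specs = {"clinical": specs["clinical"]}
        from mkfusion import MultimodalDataset
        single = MultimodalDataset(
            subject_ids=tiny_cohort.subject_ids, y=tiny_cohort.y.copy(),
            blocks={"clinical": tiny_cohort.blocks["clinical"]},
        )
        alone = loocv_fixed_weights(single, single_specs, weights=(1.0,))
        np.testing.assert_allclose(vertex.scores, alone.scores, atol=1e-8)

    def test_duplicated_separable_points_reach_full_accuracy(self):
        import pandas as pd
        from mkfusion import MultimodalDataset

        base = np.array([[5.0, 5.0], [-5.0, -5.0]])
        X = np.repeat(base, 6, axis=0) + 0.01 * np.arange(12)[:, None]
        ids = tuple(f"s{i}" for i in range(12))
        y = np.repeat([1.0, -1.0], 6)
        order = np.argsort(-y, kind="stable")
        ds = MultimodalDataset(
            subject_ids=ids, y=y,
            blocks={"m": pd.DataFrame(X, index=list(ids))},
        )
        res = loocv_fixed_weights(ds, weights=(1.0,), C=10.0)
        assert res.metrics["accuracy"] == 100.0


class TestNestedWeightSearch:
    def test_grid_restricted_to_vertex_matches_fixed_loocv(self, tiny_cohort):
        from mkfusion.evaluation import WeightGrid

        specs = default_kernel_specs(tiny_cohort)
        grid = WeightGrid(step=1.0, points=((0.0, 1.0, 0.0),))
        nested = nested_weight_search(tiny_cohort, specs, grid=grid,
                                      C_options=(1.0,), seed=5)
        fixed = loocv_fixed_weights(tiny_cohort, specs, weights=(0.0, 1.0, 0.0))
        np.testing.assert_allclose(nested.scores, fixed.scores, atol=1e-8)
        np.testing.assert_array_equal(nested.fold_weights,
                                      np.tile([0.0, 1.0, 0.0], (tiny_cohort.n, 1)))

    def test_deterministic_given_seed(self, tiny_cohort):
        specs = default_kernel_specs(tiny_cohort)
        grid = simplex_grid(3, 0.5)
        a = nested_weight_search(tiny_cohort, specs, grid=grid, seed=9)
        b = nested_weight_search(tiny_cohort, specs, grid=grid, seed=9)
        np.testing.assert_array_equal(a.scores, b.scores)
        np.testing.assert_array_equal(a.fold_weights, b.fold_weights)

    def test_held_out_subject_does_not_shape_its_own_training(self):
        """No leakage: subject i's LOOCV score must equal the score of a
        model whose standardization and fit never saw subject i's row.

        The oracle path standardizes with statistics computed by hand from
        the other subjects only, builds the kernels explicitly and fits
        directly; the two scores must coincide to solver tolerance.
        """
        spec = CohortSpec(n_case=7, n_control=7, eeg_shape=(3, 2, 1), n_pet_rois=5)
        ds = generate_cohort(spec, seed=21)
        specs = default_kernel_specs(ds)
        beta = (0.5, 0.25, 0.25)
        res = loocv_fixed_weights(ds, specs, weights=beta, C=1.0)
        from mkfusion import fit_svm, decision_function

        i = 4
        train = np.delete(np.arange(ds.n), i)
        K_tr = np.zeros((ds.n - 1, ds.n - 1))
        k_te = np.zeros(ds.n - 1)
        for w, m in zip(beta, ds.modalities):
            X = ds.blocks[m].to_numpy()
            mu = X[train].mean(axis=0)         # held-out row excluded by hand
            sd = X[train].std(axis=0)
            Z = (X - mu) / sd
            G = Z @ Z.T
            d = np.sqrt(np.diag(G))
            Gn = G / np.outer(d, d)
            K_tr += w * Gn[np.ix_(train, train)]
            k_te += w * Gn[i, train]
        model = fit_svm(K_tr, ds.y[train], C=1.0)
        oracle_score = decision_function(model, k_te[None, :])[0]
        assert res.scores[i] == pytest.approx(oracle_score, abs=1e-6)

    def test_too_small_dataset_rejected(self):
        spec = CohortSpec(n_case=3, n_control=3, eeg_shape=(2, 2, 1), n_pet_rois=3)
        ds = generate_cohort(spec, seed=0)
        with pytest.raises(ValueError, match="10"):
            nested_weight_search(ds)


class TestBaselineHarness:
    def test_unknown_method_lists_options(self, tiny_cohort):
        with pytest.raises(ValueError, match="svm_stacked"):
            baseline_harness(tiny_cohort, method="quantum_forest")

    def test_unknown_modality_rejected(self, tiny_cohort):
        with pytest.raises(ValueError, match="all_stacked"):
            baseline_harness(tiny_cohort, modality="fmri")

    def test_protocol_yields_one_prediction_per_subject(self, tiny_cohort):
        res = baseline_harness(tiny_cohort, method="svm", modality="clinical")
        assert len(res.scores) == tiny_cohort.n

    def test_stacked_svm_separable_toy(self):
        import pandas as pd
        from mkfusion import MultimodalDataset

        rng = np.random.default_rng(0)
        X1 = np.vstack([rng.normal(4, 0.1, (6, 2)), rng.normal(-4, 0.1, (6, 2))])
        X2 = rng.standard_normal((12, 3))
        ids = tuple(f"s{i}" for i in range(12))
        ds = MultimodalDataset(
            subject_ids=ids, y=np.repeat([1.0, -1.0], 6),
            blocks={"a": pd.DataFrame(X1, index=list(ids)),
                    "b": pd.DataFrame(X2, index=list(ids))},
        )
        res = baseline_harness(ds, method="svm_stacked", modality="all_stacked")
        assert res.metrics["accuracy"] == 100.0

    @pytest.mark.parametrize("method", ["random_forest", "gradient_boosting", "mlp"])
    def test_other_learners_run_loocv(self, tiny_cohort, method):
        res = baseline_harness(tiny_cohort, method=method, modality="clinical",
                               seed=1)
        assert len(res.scores) == tiny_cohort.n
        assert res.method == f"{method}:clinical"
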