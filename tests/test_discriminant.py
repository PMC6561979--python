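"""Linear-discriminant search: AUROC, Youden, CV and exhaustive enumeration."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from pulmorad.discriminant import (SingleClassError, _batch_j_auc, auroc,
                                   augment_clinical, count_subsets,
                                   evaluate_on_test, exhaustive_search,
                                   fit_linear_discriminant, holdout_cv,
                                   kernel_sensitivity, stratify_by_size,
                                   variability_fractions, youden)
from pulmorad.synthetic import generate_feature_table_direct


def pair_counting_auc(scores, y):
    """O(n^2) Mann-Whitney oracle with half-weight ties."""
    s = np.asarray(scores, float)
    y = np.asarray(y, int)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestAuroc:
    def test_worked_example(self):
        assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_all_ties_give_half(self):
        assert auroc([1.0] * 6, [0, 0, 0, 1, 1, 1]) == 0.5

    def test_negation_symmetry(self, rng):
        s = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        assert auroc(-s, y) == pytest.approx(1 - auroc(s, y))

    def test_matches_pair_counting_oracle_on_random_fixtures(self, rng):
        for trial in range(30):
            n = int(rng.integers(5, 200))
            s = rng.normal(size=n)
            if trial % 3 == 0:
                s = np.round(s, 1)  # force ties
            y = rng.integers(0, 2, n)
            y[:2] = [0, 1]
            assert auroc(s, y) == pytest.approx(pair_counting_auc(s, y),
                                                abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(SingleClassError):
            auroc([1.0, 2.0], [1, 1])


def brute_force_youden(scores, y):
    s = np.asarray(scores, float)
    y = np.asarray(y, int)
    n1, n0 = (y == 1).sum(), (y == 0).sum()
    cuts = np.concatenate([[-np.inf], np.sort(np.unique(s)), [np.inf]])
    best = -np.inf
    for c in cuts:
        pos = s >= c
        j = (pos & (y == 1)).sum() / n1 + (~pos & (y == 0)).sum() / n0 - 1
        best = max(best, j)
    return best


class TestYouden:
    def test_perfectly_separated(self):
        j, cutoff, sens, spec = youden([1, 2, 3, 4], [0, 0, 1, 1])
        assert (j, sens, spec) == (1.0, 1.0, 1.0)
        assert 2 < cutoff < 3

    def test_matches_exhaustive_threshold_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 60))
            s = np.round(rng.normal(size=n), 1)
            y = rng.integers(0, 2, n)
            y[:2] = [0, 1]
            j, *_ = youden(s, y)
            assert j == pytest.approx(brute_force_youden(s, y), abs=1e-12)

    def test_j_nonnegative(self, rng):
        for _ in range(10):
            s = rng.normal(size=20)
            y = rng.integers(0, 2, 20)
            y[:2] = [0, 1]
            assert youden(s, y)[0] >= 0


class TestLinearDiscriminant:
    def test_identity_covariance_recovers_mean_difference_direction(self, rng):
        n = 4000
        X = rng.normal(size=(n, 2))
        y = np.repeat([0, 1], n // 2)
        X[y == 1, 0] += 1.0
        model = fit_linear_discriminant(X, y)
        w = model.weights / np.linalg.norm(model.weights)
        assert abs(w[0]) > 0.97
        assert abs(w[1]) < 0.25

    def test_separable_feature_is_perfect(self):
        X = np.array([[0.0], [0.1], [0.9], [1.0]])
        y = np.array([0, 0, 1, 1])
        model = fit_linear_discriminant(X, y)
        assert model.train_auc == 1.0
        assert model.j_index == 1.0

    @pytest.mark.parametrize("delta", [1.0, 2.0, 3.0])
    def test_closed_form_auc_recovery(self, delta, rng):
        n = 2000
        X = rng.normal(size=(2 * n, 3))
        y = np.repeat([0, 1], n)
        X[y == 1, 0] += delta
        model = fit_linear_discriminant(X, y)
        assert model.train_auc == pytest.approx(norm.cdf(delta / np.sqrt(2)),
                                                abs=0.02)

    def test_single_class_raises(self):
        with pytest.raises(SingleClassError):
            fit_linear_discriminant(np.ones((4, 1)), [1, 1, 1, 1])

    def test_singular_covariance_survives_by_shrinkage(self):
        x = np.array([0.0, 0.0, 1.0, 1.0])
        X = np.column_stack([x, 2 * x])  # rank-1 covariance
        model = fit_linear_discriminant(X, [0, 0, 1, 1])
        assert np.isfinite(model.weights).all()
        assert model.train_auc == 1.0


class TestCountSubsets:
    def test_reduced_panel_scale_search_space(self):
        assert count_subsets(129, 4) == 11_009_376
        assert count_subsets(129, 4) == 129 * 128 * 127 * 126 // 24

    @pytest.mark.parametrize("p, k, expected", [(5, 2, 10), (7, 0, 1), (7, 7, 1)])
    def test_small_cases(self, p, k, expected):
        assert count_subsets(p, k) == expected

    def test_invalid_args_raise(self):
        with pytest.raises(ValueError):
            count_subsets(3, 5)


class TestHoldoutCV:
    def test_label_copy_feature_is_always_perfect(self):
        y = np.repeat([0, 1], 20)
        t = pd.DataFrame({"f": y.astype(float)})
        est = holdout_cv(t, y, ["f"], repeats=25, seed=1)
        assert est.auc_mean == 1.0
        assert est.auc_ci == (1.0, 1.0)

    def test_null_labels_center_on_half(self, rng):
        t = pd.DataFrame({"f": rng.normal(size=200)})
        y = np.repeat([0, 1], 100)
        est = holdout_cv(t, y, ["f"], repeats=200, seed=2)
        assert est.auc_mean == pytest.approx(0.5, abs=0.05)

    def test_seed_reproducibility(self, rng):
        t = pd.DataFrame(rng.normal(size=(60, 2)), columns=["a", "b"])
        y = np.repeat([0, 1], 30)
        e1 = holdout_cv(t, y, ["a", "b"], repeats=20, seed=9)
        e2 = holdout_cv(t, y, ["a", "b"], repeats=20, seed=9)
        assert np.array_equal(e1.per_repeat_aucs, e2.per_repeat_aucs)

    def test_tiny_class_cannot_stratify(self):
        t = pd.DataFrame({"f": np.arange(5.0)})
        y = np.array([0, 0, 0, 0, 1])
        with pytest.raises(SingleClassError):
            holdout_cv(t, y, ["f"], repeats=3, seed=0)


class TestExhaustiveSearch:
    def test_batch_scores_match_single_model_path(self, rng):
        X = rng.normal(size=(50, 6))
        y = np.repeat([0, 1], 25)
        X[y == 1, 2] += 1.0
        subsets = np.array(list(itertools.combinations(range(6), 3)))
        j_b, auc_b = _batch_j_auc(X, y, subsets)
        for i, sub in enumerate(subsets):
            m = fit_linear_discriminant(X[:, sub], y)
            assert auc_b[i] == pytest.approx(m.train_auc, abs=1e-12)
            assert j_b[i] == pytest.approx(m.j_index, abs=1e-12)

    def test_perfect_feature_wins_size_one(self, rng):
        y = np.repeat([0, 1], 20)
        t = pd.DataFrame(rng.normal(size=(40, 5)),
                         columns=[f"f{i}" for i in range(5)])
        t["f3"] = y + 0.01 * rng.normal(size=40)
        sr = exhaustive_search(t, y, max_dim=1, run_cv=False)
        assert sr.best.features == ("f3",)
        assert sr.best.train_auc == 1.0

    def test_size_two_search_equals_double_loop_oracle(self, rng):
        y = np.repeat([0, 1], 30)
        t = pd.DataFrame(rng.normal(size=(60, 6)),
                         columns=[f"f{i}" for i in range(6)])
        t.loc[y == 1, "f1"] += 0.8
        t.loc[y == 1, "f4"] += 0.5
        sr = exhaustive_search(t, y, max_dim=2, run_cv=False, top_m=1)
        best_pairs = [(m.features, m.j_index, m.train_auc)
                      for m, _ in sr.ranked if len(m.features) == 2]
        # independent double loop with the same ranking key
        oracle = []
        for a, b in itertools.combinations(t.columns, 2):
            m = fit_linear_discriminant(t[[a, b]].to_numpy(), y, (a, b))
            oracle.append((-m.j_index, -m.train_auc, (a, b)))
        oracle.sort()
        assert best_pairs[0][0] == oracle[0][2]
        assert best_pairs[0][1] == pytest.approx(-oracle[0][0])

    def test_search_space_size_accounting(self, rng):
        y = np.repeat([0, 1], 15)
        t = pd.DataFrame(rng.normal(size=(30, 7)),
                         columns=[f"f{i}" for i in range(7)])
        sr = exhaustive_search(t, y, max_dim=3, run_cv=False)
        assert sr.search_space_size == 7 + 21 + 35

    def test_empty_pool_raises(self, rng):
        t = pd.DataFrame({"a": rng.normal(size=10)})
        with pytest.raises(ValueError, match="pool"):
            exhaustive_search(t, np.repeat([0, 1], 5), feature_pool=[])


class TestEvaluateOnTest:
    def test_frozen_auc_equals_pair_counting_oracle(self, rng):
        y = np.repeat([0, 1], 25)
        t = pd.DataFrame(rng.normal(size=(50, 3)), columns=["a", "b", "c"])
        t.loc[y == 1, "a"] += 1.0
        model = fit_linear_discriminant(t.to_numpy(), y, ("a", "b", "c"))
        y2 = np.repeat([0, 1], 20)
        t2 = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
        t2.loc[y2 == 1, "a"] += 1.0
        est = evaluate_on_test(model, t2, y2, repeats=100, seed=0)
        assert est.auc_mean == pytest.approx(
            pair_counting_auc(model.score(t2), y2), abs=1e-12)
        assert est.auc_ci[0] <= est.auc_mean <= est.auc_ci[1]

    def test_identical_separable_test_set(self):
        y = np.repeat([0, 1], 10)
        t = pd.DataFrame({"f": y.astype(float)})
        model = fit_linear_discriminant(t.to_numpy(), y, ("f",))
        est = evaluate_on_test(model, t, y, repeats=50, seed=0)
        assert est.auc_mean == 1.0

    def test_missing_feature_column_raises(self, rng):
        y = np.repeat([0, 1], 10)
        t = pd.DataFrame({"f": rng.normal(size=20)})
        model = fit_linear_discriminant(t.to_numpy(), y, ("f",))
        with pytest.raises(KeyError):
            evaluate_on_test(model, t.rename(columns={"f": "g"}), y)


class TestClinicalAugmentation:
    def _tables(self, rng, n=60):
        y = np.repeat([0, 1], n // 2)
        t = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"],
                         index=[f"S{i}" for i in range(n)])
        t.loc[y == 1, "a"] += 1.0
        clin = pd.DataFrame({
            "age": rng.normal(64, 5, n), "sex": rng.integers(0, 2, n),
            "pack_years": rng.normal(60, 20, n),
            "smoke_status": rng.integers(0, 2, n)}, index=t.index)
        return t, clin, y

    def test_image_only_results_unchanged_by_augmentation(self, rng):
        t, clin, y = self._tables(rng)
        aug = augment_clinical(t, clin)
        sr1 = exhaustive_search(t, y, max_dim=2, run_cv=False,
                                feature_pool=["a", "b", "c"])
        sr2 = exhaustive_search(aug, y, max_dim=2, run_cv=False,
                                feature_pool=["a", "b", "c"])
        assert sr1.best.features == sr2.best.features
        assert sr1.best.train_auc == sr2.best.train_auc

    def test_null_covariates_do_not_change_auc_much(self, rng):
        t, clin, y = self._tables(rng, n=200)
        aug = augment_clinical(t, clin)
        base = fit_linear_discriminant(t[["a"]].to_numpy(), y).train_auc
        combo = fit_linear_discriminant(
            aug[["a", "clin_age", "clin_sex"]].to_numpy(), y).train_auc
        assert combo == pytest.approx(base, abs=0.07)

    def test_sex_code_flip_leaves_auc_unchanged(self, rng):
        t, clin, y = self._tables(rng)
        a1 = augment_clinical(t, clin)
        clin2 = clin.assign(sex=1 - clin["sex"])
        a2 = augment_clinical(t, clin2)
        m1 = fit_linear_discriminant(a1[["a", "clin_sex"]].to_numpy(), y)
        m2 = fit_linear_discriminant(a2[["a", "clin_sex"]].to_numpy(), y)
        assert m1.train_auc == pytest.approx(m2.train_auc, abs=1e-12)

    def test_missing_values_raise(self, rng):
        t, clin, y = self._tables(rng)
        clin.loc[clin.index[3], "age"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            augment_clinical(t, clin)


class TestSizeStrata:
    def test_boundary_conventions(self):
        t = pd.DataFrame({"x": range(5)},
                         index=["s1", "s2", "s3", "s4", "s5"])
        d = [4.0, 12.0, 12.1, 30.0, 31.0]
        r1 = stratify_by_size(t, d, "R1")
        r2 = stratify_by_size(t, d, "R2")
        assert list(r1.index) == ["s1", "s2"]   # 12.0 is indeterminate
        assert list(r2.index) == ["s3", "s4"]   # >12 to 30; 31 excluded
        assert set(r1.index).isdisjoint(r2.index)
        assert len(stratify_by_size(t, d, "all")) == 5


class TestKernelSensitivity:
    def test_identical_tables_have_zero_delta(self, rng):
        y = np.repeat([0, 1], 25)
        t = pd.DataFrame(rng.normal(size=(50, 4)),
                         columns=[f"f{i}" for i in range(4)])
        t.loc[y == 1] += 0.5
        out = kernel_sensitivity(list(t.columns), t, t.copy(), y)
        assert np.allclose(out["delta_auc"], 0.0)
        assert out.attrs["fractions"]["overall"]["below_5pct"] == 1.0

    def test_heavy_noise_raises_median_delta(self, rng):
        y = np.repeat([0, 1], 40)
        t = pd.DataFrame(rng.normal(size=(80, 6)),
                         columns=[f"f{i}" for i in range(6)])
        t.loc[y == 1] += 0.8
        noisy = t + rng.normal(0, 4.0, size=t.shape)
        base = kernel_sensitivity(list(t.columns), t, t.copy(), y)
        pert = kernel_sensitivity(list(t.columns), t, noisy, y)
        assert pert["delta_auc"].median() > base["delta_auc"].median()

    def test_hand_made_fraction_arithmetic(self):
        fr = variability_fractions(pd.Series([0.02, 0.06, 0.12]))
        assert fr["overall"]["below_5pct"] == pytest.approx(1 / 3)
        assert fr["overall"]["below_10pct"] == pytest.approx(2 / 3)

    def test_subject_mismatch_raises(self, rng):
        y = np.repeat([0, 1], 5)
        t = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        t2 = t.copy()
        t2.index = [i + 100 for i in range(10)]
        with pytest.raises(ValueError, match="subject"):
            kernel_sensitivity(["a"], t, t2, y)


def test_planted_gaussian_feature_reaches_closed_form_auc():
    test, _, y = generate_feature_table_direct(
        500, 500, p_noise=0, planted=[(3.0, 1)], seed=11)
    a = auroc(test["planted_000"], y)
    assert a == pytest.approx(norm.cdf(3.0 / np.sqrt(2)), abs=0.01)
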