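"""Classification harness: splitting, metrics against brute-force
oracles, experiment aggregation, statistical comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest

from reentryforge.ml import (MODEL_NAMES, ExperimentConfig,
                             compare_populations, compute_metrics,
                             confusion_counts, make_classifier,
                             run_experiment, split_and_standardize,
                             train_and_predict, tree_importance)


def _dataset(n, rng, informative=True):
    X = rng.normal(size=(n, 4))
    if informative:
        y = (X[:, 3] + 0.3 * X[:, 1] + rng.normal(0, 0.3, n) > 0)
    else:
        y = rng.integers(0, 2, n).astype(bool)
    df = pd.DataFrame(X, columns=["seg_vol", "seg_isch_pct", "total_vol",
                                  "total_isch_vol"])
    df["label"] = y.astype(int)
    return df


class TestSplitAndStandardize:
    def test_510_rows_split_357_153(self, rng):
        ds = _dataset(510, rng)
        Xtr, ytr, Xte, yte = split_and_standardize(
            ds, ExperimentConfig(), rng)
        assert len(ytr) == 357 and len(yte) == 153

    def test_per_split_standardization_zero_mean_unit_sd(self, rng):
        ds = _dataset(200, rng)
        Xtr, _, Xte, _ = split_and_standardize(ds, ExperimentConfig(), rng)
        np.testing.assert_allclose(Xtr.mean(0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Xtr.std(0), 1.0, rtol=1e-12)
        np.testing.assert_allclose(Xte.mean(0), 0.0, atol=1e-12)

    def test_train_fit_mode_leaves_test_unnormalized(self, rng):
        ds = _dataset(200, rng)
        cfg = ExperimentConfig(standardization="train-fit")
        _, _, Xte, _ = split_and_standardize(ds, cfg, rng)
        # test means generally differ from 0 when scaled by train stats
        assert np.abs(Xte.mean(0)).max() > 1e-6

    def test_same_seed_gives_identical_split(self, rng):
        ds = _dataset(100, rng)
        cfg = ExperimentConfig()
        a = split_and_standardize(ds, cfg, np.random.default_rng(5))
        b = split_and_standardize(ds, cfg, np.random.default_rng(5))
        np.testing.assert_array_equal(a[1], b[1])
        np.testing.assert_allclose(a[0], b[0])

    def test_zero_variance_feature_warned_and_centred(self, rng):
        ds = _dataset(100, rng)
        ds["total_vol"] = 3.0
        with pytest.warns(UserWarning, match="zero-variance"):
            Xtr, *_ = split_and_standardize(ds, ExperimentConfig(), rng)
        assert np.allclose(Xtr[:, 2], 0.0)

    def test_tiny_dataset_rejected(self, rng):
        with pytest.raises(ValueError):
            split_and_standardize(_dataset(5, rng), ExperimentConfig(),
                                  rng)


class TestTrainAndPredict:
    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_threshold_separable_data_learned_perfectly(self, name, rng):
        """One-threshold separable labels: every classifier, including
        the depth-limited tree, reaches train accuracy 1.0. The margin
        feature dominates the (low-amplitude) noise features, and n is
        large enough that the narrow deep net gets sufficient minibatch
        updates within its 25 epochs."""
        n = 600
        x = np.concatenate([rng.uniform(-2, -0.5, n // 2),
                            rng.uniform(0.5, 2, n // 2)])
        X = np.column_stack([x, rng.normal(size=n) * 0.1,
                             rng.normal(size=n) * 0.1,
                             rng.normal(size=n) * 0.1])
        y = (x > 0).astype(int)
        scores, labels, _ = train_and_predict(name, X, y, X, seed=0)
        assert (labels == y).mean() == 1.0

    def test_constant_features_give_prior_for_logistic(self, rng):
        n = 400
        X = np.zeros((n, 4))
        y = (rng.random(n) < 0.3).astype(int)
        scores, _, _ = train_and_predict("logistic", X, y, X[:50], seed=0)
        assert np.allclose(scores, y.mean(), atol=0.02)

    def test_identical_train_test_beats_majority_rate(self, rng):
        ds = _dataset(300, rng)
        X = ds.iloc[:, :4].to_numpy()
        y = ds["label"].to_numpy()
        for name in ("knn", "tree", "logistic"):
            _, labels, _ = train_and_predict(name, X, y, X, seed=0)
            assert (labels == y).mean() >= max(y.mean(), 1 - y.mean())

    def test_single_class_training_rejected(self):
        X = np.zeros((20, 4))
        with pytest.raises(ValueError, match="single class"):
            train_and_predict("knn", X, np.zeros(20, dtype=int), X)


def brute_force_metrics(scores, y, thr=0.5):
    """Independent oracle: explicit enumeration of the confusion matrix
    and pair-counting AUC (probability a positive outranks a negative,
    ties at half)."""
    y = np.asarray(y)
    pred = (np.asarray(scores) >= thr).astype(int)
    tp = sum(1 for a, b in zip(y, pred) if a == 1 and b == 1)
    fp = sum(1 for a, b in zip(y, pred) if a == 0 and b == 1)
    fn = sum(1 for a, b in zip(y, pred) if a == 1 and b == 0)
    tn = sum(1 for a, b in zip(y, pred) if a == 0 and b == 0)
    acc = (tp + tn) / len(y)
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    if pos and neg:
        wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
                   for p in pos for q in neg)
        auc = wins / (len(pos) * len(neg))
    else:
        auc = np.nan
    return dict(tp=tp, fp=fp, fn=fn, tn=tn, accuracy=acc, auc=auc)


class TestMetricOracle:
    def test_printed_formula_example(self):
        # TP=9 FP=1 FN=3 TN=7
        y = [1] * 12 + [0] * 8
        scores = [0.9] * 9 + [0.1] * 3 + [0.8] + [0.1] * 7
        m = compute_metrics(scores, y)
        assert (m["tp"], m["fp"], m["fn"], m["tn"]) == (9, 1, 3, 7)
        assert m["precision"] == pytest.approx(0.90)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["accuracy"] == pytest.approx(0.80)

    def test_perfect_scores(self):
        y = [0, 0, 1, 1]
        m = compute_metrics([0.1, 0.2, 0.8, 0.9], y)
        assert m["auc"] == 1.0 and m["average_precision"] == 1.0

    def test_exhaustive_small_fixtures_match_brute_force(self):
        """All 2^4 label patterns x 3 score vectors: accuracy and
        confusion counts match enumeration; AUC equals the pair-counting
        (Mann-Whitney) statistic."""
        score_sets = [(0.1, 0.4, 0.6, 0.9), (0.9, 0.1, 0.8, 0.2),
                      (0.5, 0.5, 0.7, 0.2)]
        for labels in itertools.product([0, 1], repeat=4):
            for scores in score_sets:
                m = compute_metrics(scores, labels)
                ref = brute_force_metrics(scores, labels)
                for key in ("tp", "fp", "fn", "tn"):
                    assert m[key] == ref[key], (labels, scores, key)
                assert m["accuracy"] == pytest.approx(ref["accuracy"])
                if 0 < sum(labels) < 4:
                    assert m["auc"] == pytest.approx(ref["auc"])
                else:
                    assert np.isnan(m["auc"])

    def test_random_scores_give_half_auc(self, rng):
        n = 10_000
        y = rng.integers(0, 2, n)
        s = rng.random(n)
        m = compute_metrics(s, y)
        assert m["auc"] == pytest.approx(0.5, abs=0.02)
        ref = brute_force_metrics(s[:2000], y[:2000])
        assert compute_metrics(s[:2000], y[:2000])["auc"] == \
            pytest.approx(ref["auc"], abs=1e-12)

    def test_one_class_labels_leave_auc_missing(self):
        m = compute_metrics([0.2, 0.8], [1, 1])
        assert np.isnan(m["auc"]) and np.isnan(m["average_precision"])


class TestRunExperiment:
    def test_single_run_has_zero_sd(self, rng):
        ds = _dataset(120, rng)
        cfg = ExperimentConfig(models=("knn", "tree"), n_runs=1)
        per_run, summary = run_experiment(ds, cfg, seed=0)
        assert len(per_run) == 2
        assert summary[("accuracy", "std")].isna().all() or \
            (summary[("accuracy", "std")].fillna(0) == 0).all()

    def test_mean_within_min_max(self, rng):
        ds = _dataset(200, rng)
        cfg = ExperimentConfig(models=("knn", "logistic"), n_runs=8)
        _, summary = run_experiment(ds, cfg, seed=1)
        acc = summary["accuracy"]
        assert ((acc["mean"] >= acc["min"]) & (acc["mean"] <= acc["max"])
                ).all()

    def test_roc_bands_have_grid_shape(self, rng):
        ds = _dataset(200, rng)
        cfg = ExperimentConfig(models=("logistic",), n_runs=5)
        _, _, roc = run_experiment(ds, cfg, seed=1, collect_roc=True)
        grid, mean, lo, hi = roc["logistic"]
        assert grid.shape == mean.shape == lo.shape == hi.shape
        assert (lo <= hi).all()
        assert mean[0] <= mean[-1]

    def test_deterministic_given_seed(self, rng):
        ds = _dataset(150, rng)
        cfg = ExperimentConfig(models=("tree", "logistic"), n_runs=3)
        a, _ = run_experiment(ds, cfg, seed=9)
        b, _ = run_experiment(ds, cfg, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestComparePopulations:
    def _arms(self, shift, sd_b=0.01, n=100, seed=0):
        rng = np.random.default_rng(seed)
        a = pd.DataFrame({"model": "knn",
                          "accuracy": rng.normal(0.85, 0.01, n)})
        b = pd.DataFrame({"model": "knn",
                          "accuracy": rng.normal(0.85 + shift, sd_b, n)})
        return a, b

    def test_identical_arms_null_p_near_half(self):
        rng = np.random.default_rng(0)
        ps = []
        for s in range(40):
            a, b = self._arms(0.0, sd_b=0.01, n=50, seed=s)
            ps.append(compare_populations(a, b)["p_t_one_sided"].iloc[0])
        # under the null the one-sided p is uniform: mean near 0.5
        assert abs(np.mean(ps) - 0.5) < 0.15

    def test_clear_shift_is_overwhelming(self):
        a, b = self._arms(0.05, sd_b=0.01)
        out = compare_populations(a, b)
        assert out["p_t_one_sided"].iloc[0] < 1e-10
        assert out["p_f_one_sided"].iloc[0] == pytest.approx(
            out["p_f_one_sided"].iloc[0])

    def test_swapped_arms_p_above_half(self):
        a, b = self._arms(0.05)
        out = compare_populations(b, a)  # "augmented" is the worse arm
        assert out["p_t_one_sided"].iloc[0] > 0.5

    def test_variance_reduction_detected(self):
        a, b = self._arms(0.0, sd_b=0.002)
        out = compare_populations(a, b)
        assert out["p_f_one_sided"].iloc[0] < 1e-6

    def test_too_few_runs_rejected(self):
        a = pd.DataFrame({"model": "knn", "accuracy": [0.8]})
        with pytest.raises(ValueError):
            compare_populations(a, a)


class TestTreeImportance:
    def test_single_informative_feature_gets_full_importance(self, rng):
        X = np.column_stack([rng.normal(size=200)] * 3
                            + [np.linspace(-1, 1, 200)])
        y = (X[:, 3] > 0).astype(int)
        _, _, clf = train_and_predict("tree", X, y, X[:5], seed=0)
        imp = tree_importance(clf)
        assert imp["feature"].iloc[0] == "total_isch_vol"
        assert imp["importance"].iloc[0] == pytest.approx(1.0)

    def test_importances_sum_to_one(self, rng):
        ds = _dataset(300, rng)
        X = ds.iloc[:, :4].to_numpy()
        y = ds["label"].to_numpy()
        _, _, clf = train_and_predict("tree", X, y, X[:5], seed=0)
        imp = tree_importance(clf)
        assert imp["importance"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_volume_driven_labels_rank_volume_first(self, rng):
        """Generative fixture: inducibility rises with total ischemic
        volume, as the simulated cohort reports — the tree must rank that
        feature first."""
        n = 600
        X = rng.normal(size=(n, 4))
        y = (X[:, 3] * 2.0 + 0.2 * X[:, 1]
             + rng.normal(0, 0.5, n) > 0).astype(int)
        _, _, clf = train_and_predict("tree", X, y, X[:5], seed=0)
        imp = tree_importance(clf)
        assert imp["feature"].iloc[0] == "total_isch_vol"

    def test_unfitted_tree_rejected(self):
        with pytest.raises(ValueError):
            tree_importance(make_classifier("tree"))
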