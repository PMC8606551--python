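"""Arrhythmia-risk classification harness.

Seven classifiers — k-nearest neighbours (k=5), Gaussian-kernel SVM (C=2),
logistic regression, depth-3 decision tree, gradient-boosted trees, and
3- and 4-hidden-layer multilayer perceptrons (32-17-8 and 32-17-8-8 ReLU
units) — are each trained on 70% of the (model, segment) rows and
evaluated on the held-out 30%, repeated over many random splits.
Accuracy, precision and sensitivity at a 0.5 threshold, average precision
and ROC AUC are aggregated per model (mean, SD, max, min), and baseline
vs augmented populations are compared with a one-sided t-test on mean
accuracy and a one-sided F-test on accuracy variance.

Standardization follows the split-then-standardize scheme by default:
each split is standardized with its own mean and SD ("per-split" mode,
leakage-free but unconventional); a conventional "train-fit" mode that
applies train statistics to both splits is provided as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .features import FEATURE_COLUMNS

__all__ = ["ExperimentConfig", "MODEL_NAMES", "make_classifier",
           "split_and_standardize", "train_and_predict", "compute_metrics",
           "confusion_counts", "run_experiment", "compare_populations",
           "tree_importance"]

MODEL_NAMES = ("knn", "svm", "logistic", "tree", "xgboost", "nn3", "nn4")

# Gradient-boosting defaults pinned to decouple results from library drift.
XGB_PARAMS = dict(n_estimators=100, max_depth=6, learning_rate=0.3,
                  subsample=1.0, colsample_bytree=1.0, reg_lambda=1.0,
                  objective="binary:logistic", eval_metric="logloss",
                  tree_method="hist", n_jobs=1, verbosity=0)

# The emulated NN recipe decays its 0.01 learning rate by 0.9 per 1e5
# steps — negligible over 25 epochs — so a constant rate is faithful.
MLP_PARAMS = dict(activation="relu", solver="sgd", momentum=0.0,
                  learning_rate="constant", learning_rate_init=0.01,
                  batch_size=20, max_iter=25, tol=0.0)


@dataclass
class ExperimentConfig:
    models: tuple = MODEL_NAMES
    train_fraction: float = 0.70
    n_runs: int = 100
    standardization: str = "per-split"   # or "train-fit"
    threshold: float = 0.5
    feature_columns: tuple = FEATURE_COLUMNS
    roc_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 1.0, 101))

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.standardization not in ("per-split", "train-fit"):
            raise ValueError("standardization must be 'per-split' or "
                             "'train-fit'")


def make_classifier(name: str, seed: int = 0):
    """Instantiate one of the seven classifiers with its fixed
    hyperparameters."""
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "svm":
        return SVC(C=2.0, kernel="rbf", probability=True,
                   random_state=seed)
    if name == "logistic":
        return LogisticRegression(max_iter=1000)
    if name == "tree":
        return DecisionTreeClassifier(max_depth=3, random_state=seed)
    if name == "xgboost":
        return XGBClassifier(random_state=seed, **XGB_PARAMS)
    if name == "nn3":
        return MLPClassifier(hidden_layer_sizes=(32, 17, 8),
                             random_state=seed, **MLP_PARAMS)
    if name == "nn4":
        return MLPClassifier(hidden_layer_sizes=(32, 17, 8, 8),
                             random_state=seed, **MLP_PARAMS)
    raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")


def _standardize(X: np.ndarray, mean, sd):
    sd = sd.copy()
    zero = sd == 0
    if zero.any():
        warnings.warn("zero-variance feature(s) left centred only",
                      stacklevel=3)
        sd[zero] = 1.0
    return (X - mean) / sd


def split_and_standardize(dataset: pd.DataFrame, cfg: ExperimentConfig,
                          rng: np.random.Generator):
    """Random 70/30 row split with per-split or train-fit standardization.

    Returns ``(X_train, y_train, X_test, y_test)``; the train size is
    ``floor(train_fraction * n)``."""
    if len(dataset) < 10:
        raise ValueError("dataset must have at least 10 rows")
    X = dataset.loc[:, list(cfg.feature_columns)].to_numpy(dtype=float)
    y = dataset["label"].to_numpy(dtype=int)
    n = len(y)
    perm = rng.permutation(n)
    n_train = int(np.floor(cfg.train_fraction * n))
    tr, te = perm[:n_train], perm[n_train:]
    Xtr, Xte = X[tr], X[te]
    if cfg.standardization == "per-split":
        Xtr = _standardize(Xtr, Xtr.mean(0), Xtr.std(0))
        Xte = _standardize(Xte, Xte.mean(0), Xte.std(0))
    else:
        mu, sd = Xtr.mean(0), Xtr.std(0)
        Xtr = _standardize(Xtr, mu, sd)
        Xte = _standardize(Xte, mu, sd)
    return Xtr, y[tr], Xte, y[te]


def train_and_predict(name: str, Xtr, ytr, Xte, seed: int = 0,
                      threshold: float = 0.5):
    """Fit one classifier; return (positive-class scores, hard labels)."""
    if len(np.unique(ytr)) < 2:
        raise ValueError("training set contains a single class")
    clf = make_classifier(name, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence at 25 epochs
        clf.fit(Xtr, ytr)
    scores = clf.predict_proba(Xte)[:, 1]
    return scores, (scores >= threshold).astype(int), clf


def confusion_counts(y_true, y_pred):
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    return tp, fp, fn, tn


def compute_metrics(scores, y_true, threshold: float = 0.5) -> dict:
    """Accuracy, precision and sensitivity at the threshold, plus AP and
    AUC from the scores. One-class test labels leave AP/AUC as NaN."""
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    y_pred = (scores >= threshold).astype(int)
    tp, fp, fn, tn = confusion_counts(y_true, y_pred)
    n = tp + fp + fn + tn
    out = {
        "accuracy": (tp + tn) / n,
        "precision": tp / (tp + fp) if (tp + fp) else np.nan,
        "sensitivity": tp / (tp + fn) if (tp + fn) else np.nan,
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
    }
    if len(np.unique(y_true)) < 2:
        out["average_precision"] = np.nan
        out["auc"] = np.nan
    else:
        out["average_precision"] = average_precision_score(y_true, scores)
        out["auc"] = roc_auc_score(y_true, scores)
    return out


def run_experiment(dataset: pd.DataFrame, cfg: ExperimentConfig | None = None,
                   seed: int = 0, collect_roc: bool = False):
    """The repeated-split experiment over all configured classifiers.

    Returns ``(per_run, summary[, roc])``: ``per_run`` has one row per
    (model, run) with all metrics; ``summary`` aggregates mean, SD, max,
    min per model and metric; with ``collect_roc`` a third element maps
    model name to (fpr_grid, mean_tpr, lo_tpr, hi_tpr) 95% bands across
    runs. Failed runs are logged, excluded and counted.
    """
    cfg = cfg or ExperimentConfig()
    rows = []
    roc_tprs = {m: [] for m in cfg.models}
    n_failed = 0
    for run in range(cfg.n_runs):
        rng = np.random.default_rng((seed, run))
        Xtr, ytr, Xte, yte = split_and_standardize(dataset, cfg, rng)
        for name in cfg.models:
            try:
                scores, _, _ = train_and_predict(
                    name, Xtr, ytr, Xte, seed=(seed * 1009 + run) % (2**31),
                    threshold=cfg.threshold)
            except ValueError:
                n_failed += 1
                continue
            m = compute_metrics(scores, yte, cfg.threshold)
            m.update(model=name, run=run)
            rows.append(m)
            if collect_roc and len(np.unique(yte)) == 2:
                fpr, tpr, _ = roc_curve(yte, scores)
                roc_tprs[name].append(
                    np.interp(cfg.roc_grid, fpr, tpr))
    per_run = pd.DataFrame(rows)
    metrics = ["accuracy", "precision", "sensitivity",
               "average_precision", "auc"]
    summary = per_run.groupby("model")[metrics].agg(
        ["mean", "std", "max", "min"])
    summary.attrs["n_failed"] = n_failed
    if not collect_roc:
        return per_run, summary
    roc = {}
    for name, tprs in roc_tprs.items():
        if not tprs:
            continue
        arr = np.asarray(tprs)
        roc[name] = (cfg.roc_grid, arr.mean(0),
                     np.percentile(arr, 2.5, axis=0),
                     np.percentile(arr, 97.5, axis=0))
    return per_run, summary, roc


def compare_populations(per_run_baseline: pd.DataFrame,
                        per_run_augmented: pd.DataFrame,
                        metric: str = "accuracy") -> pd.DataFrame:
    """Baseline-vs-augmented statistical comparison, per classifier.

    One-sided Welch t-test for improved mean (augmented > baseline) and
    one-sided F-test for reduced variance (augmented < baseline); the
    two-sided t-test p-value is reported alongside. Zero variance in
    either arm leaves the F-test NaN.
    """
    rows = []
    models = sorted(set(per_run_baseline["model"])
                    & set(per_run_augmented["model"]))
    for name in models:
        a = per_run_baseline.loc[per_run_baseline["model"] == name,
                                 metric].to_numpy()
        b = per_run_augmented.loc[per_run_augmented["model"] == name,
                                  metric].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need >= 2 runs per arm")
        t_res = stats.ttest_ind(b, a, equal_var=False,
                                alternative="greater")
        t2 = stats.ttest_ind(b, a, equal_var=False)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        if va == 0 or vb == 0:
            p_f = np.nan
        else:
            F = vb / va  # < 1 when augmented variance is smaller
            p_f = stats.f.cdf(F, len(b) - 1, len(a) - 1)
        rows.append({
            "model": name,
            "mean_baseline": a.mean(), "mean_augmented": b.mean(),
            "sd_baseline": a.std(ddof=1), "sd_augmented": b.std(ddof=1),
            "p_t_one_sided": t_res.pvalue, "p_t_two_sided": t2.pvalue,
            "p_f_one_sided": p_f,
        })
    return pd.DataFrame(rows)


def tree_importance(clf: DecisionTreeClassifier,
                    feature_names=FEATURE_COLUMNS) -> pd.DataFrame:
    """Impurity-decrease importances of a fitted tree, ranked descending."""
    if not hasattr(clf, "tree_"):
        raise ValueError("tree is not fitted")
    imp = clf.feature_importances_
    df = pd.DataFrame({"feature": list(feature_names), "importance": imp})
    return df.sort_values("importance", ascending=False,
                          ignore_index=True)
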