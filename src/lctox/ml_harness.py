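"""Cross-validated experiment engine for the toxicity classifiers.

Runs stratified k-fold cross-validation with optional categorical SMOTE
oversampling of the minority class inside each training fold, over a grid
of 7 feature-family combinations x 4 algorithms x {with, without} SMOTE =
56 experiments.  Reports sensitivity, specificity, accuracy, balanced
accuracy, F1 and AUC from pooled out-of-fold scores, the Youden-optimal
operating point, an information-gain feature ranking with a removal
cutoff, and the two control experiments: incremental top-feature
classifiers and the random-label (null signal) overfitting check.

The positive class is ``tox`` throughout.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder
from sklearn.tree import DecisionTreeClassifier

from .feature_extraction import FeatureDescriptor, FeatureMatrix, value_level_name

logger = logging.getLogger(__name__)

ALGORITHMS = ("bayes_net", "logistic", "tree_j48_like", "random_forest")

#: the 7 non-empty feature-family combinations of the experiment grid
FAMILY_COMBINATIONS: tuple[tuple[str, ...], ...] = (
    ("AMP",), ("MAP",), ("DAP",),
    ("AMP", "MAP"), ("AMP", "DAP"), ("MAP", "DAP"),
    ("AMP", "MAP", "DAP"),
)


@dataclass(frozen=True)
class ExperimentConfig:
    families: tuple[str, ...]
    algorithm: str = "random_forest"
    smote: bool = False
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("families must be non-empty")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass(frozen=True)
class ExperimentReport:
    config: ExperimentConfig
    auc: float
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    balanced_accuracy: float | None
    f1: float | None
    confusion: tuple[int, int, int, int]  # TP, FP, TN, FN
    per_fold: tuple[dict, ...]
    youden: tuple[float, float, float, float]  # threshold, J, Se, Sp
    oof_scores: tuple[float, ...] = ()
    oof_labels: tuple[int, ...] = ()


@dataclass(frozen=True)
class RankedFeature:
    descriptor: FeatureDescriptor
    info_gain_bits: float
    family_rank: int
    general_rank: int
    occurrence: tuple[int, int]  # (count in tox, count in nox)


# ---------------------------------------------------------------------------
# classifier backends

def make_classifier(algorithm: str, seed: int):
    """Modern equivalents of the four learners; one-hot input is assumed.

    Exact parity with any particular legacy toolkit is not promised — the
    grid structure, CV protocol and metric definitions are what carry over.
    """
    if algorithm == "bayes_net":
        return BernoulliNB()
    if algorithm == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if algorithm == "tree_j48_like":
        return DecisionTreeClassifier(min_samples_leaf=2, random_state=seed)
    if algorithm == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def make_pipeline(algorithm: str, seed: int) -> Pipeline:
    return Pipeline([
        ("onehot", OneHotEncoder(handle_unknown="ignore", sparse_output=True)),
        ("clf", make_classifier(algorithm, seed)),
    ])


# ---------------------------------------------------------------------------
# categorical SMOTE

def smote_nominal(X: pd.DataFrame, n_synthetic: int, rng: np.random.Generator,
                  k: int = 5) -> tuple[pd.DataFrame, list[list]]:
    """Synthetic minority oversampling for nominal features.

    Each synthetic sample picks a random seed row and sets every feature to
    the majority value among the seed's k Hamming-nearest neighbours within
    ``X`` (ties: lexicographically smallest value).  Returns the synthetic
    rows plus, per row, the index labels of the donors used — the hook the
    leakage guard tests against.
    """
    if len(X) < 2:
        raise ValueError("need at least 2 minority samples for SMOTE")
    arr = X.to_numpy(dtype=object)
    n, p = arr.shape
    k_eff = min(k, n - 1)
    rows, donors = [], []
    for _ in range(n_synthetic):
        base = int(rng.integers(n))
        dist = (arr != arr[base]).sum(axis=1)
        dist[base] = p + 1  # exclude the seed itself from its neighbour set
        order = np.lexsort((np.arange(n), dist))
        neigh = order[:k_eff]
        votes = arr[neigh]
        new = []
        for col in range(p):
            vals, cnt = np.unique(votes[:, col].astype(str), return_counts=True)
            new.append(sorted(vals[cnt == cnt.max()])[0])
        rows.append(new)
        donors.append([X.index[base]] + [X.index[i] for i in neigh])
    synth = pd.DataFrame(rows, columns=X.columns,
                         index=[f"synthetic_{i}" for i in range(n_synthetic)])
    return synth, donors


def balance_training_fold(X: pd.DataFrame, y: pd.Series,
                          rng: np.random.Generator, k: int = 5
                          ) -> tuple[pd.DataFrame, pd.Series, list[list]]:
    """Oversample the minority class to parity with SMOTE; donors reported."""
    counts = y.value_counts()
    minority = counts.idxmin()
    deficit = int(counts.max() - counts.min())
    if deficit == 0:
        return X, y, []
    synth, donors = smote_nominal(X[y == minority], deficit, rng, k=k)
    X_bal = pd.concat([X, synth])
    y_bal = pd.concat([y, pd.Series(minority, index=synth.index)])
    return X_bal, y_bal, donors


# ---------------------------------------------------------------------------
# metrics

def _safe_div(num: float, den: float) -> float | None:
    return num / den if den else None


def compute_metrics(tp: int, fp: int, tn: int, fn: int,
                    scores: Sequence[float] | None = None,
                    labels: Sequence[int] | None = None) -> dict:
    """The six performance metrics; undefined ratios are None, not zero.

    Sensitivity TP/(TP+FN); specificity TN/(TN+FP); accuracy; balanced
    accuracy (mean of Se and Sp); F1 = 2TP/(2TP+FP+FN); AUC as the rank
    statistic over pooled scores when given.
    """
    se = _safe_div(tp, tp + fn)
    sp = _safe_div(tn, tn + fp)
    out = {
        "sensitivity": se,
        "specificity": sp,
        "accuracy": _safe_div(tp + tn, tp + fp + tn + fn),
        "balanced_accuracy": (se + sp) / 2 if se is not None and sp is not None else None,
        "f1": _safe_div(2 * tp, 2 * tp + fp + fn),
    }
    if scores is not None and labels is not None:
        labels = np.asarray(labels)
        if len(set(labels.tolist())) < 2:
            out["auc"] = None
        else:
            out["auc"] = float(roc_auc_score(labels, scores))
    return out


def youden_optimize(oof_scores: Sequence[float], labels: Sequence[int]
                    ) -> tuple[float, float, float, float]:
    """Maximize J = Se(c) + Sp(c) - 1 over all unique score cutpoints.

    A sequence is called tox when its score >= c.  Ties on J prefer the
    higher sensitivity, then the lower threshold.
    """
    scores = np.asarray(oof_scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if y.min() == y.max():
        raise ValueError("youden_optimize needs both classes")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    best = None
    for c in sorted(set(scores.tolist())):
        pred = scores >= c
        se = (pred & (y == 1)).sum() / n_pos
        sp = (~pred & (y == 0)).sum() / n_neg
        j = se + sp - 1
        key = (j, se, -c)
        if best is None or key > best[0]:
            best = (key, (float(c), float(j), float(se), float(sp)))
    return best[1]


def youden_index(sensitivity: float, specificity: float) -> float:
    """J at a fixed operating point: Se + Sp - 1."""
    return sensitivity + specificity - 1


def random_classifier_probability(n_correct: int, n_total: int, p: float = 0.5
                                  ) -> float:
    """Binomial point probability of exactly ``n_correct`` hits by chance."""
    return float(sps.binom.pmf(n_correct, n_total, p))


# ---------------------------------------------------------------------------
# cross-validation

def _encode_labels(labels: pd.Series) -> pd.Series:
    bad = set(labels.unique()) - {"tox", "nox"}
    if bad:
        raise ValueError(f"training labels must be tox/nox, found {sorted(bad)}")
    return (labels == "tox").astype(int)


def crossvalidate(matrix: FeatureMatrix, config: ExperimentConfig,
                  _donor_log: list | None = None,
                  select_columns: bool = True) -> ExperimentReport:
    """Stratified k-fold CV; SMOTE (when on) only ever sees training rows.

    Out-of-fold tox-probabilities are pooled across folds to produce the
    report's metrics (threshold 0.5 for the confusion matrix) and the
    Youden operating point.  ``select_columns=False`` uses the matrix's
    columns as-is (for pre-sliced designs such as top-feature prefixes).
    """
    view = matrix.training_view()
    if select_columns and set(config.families) != {"GLVJ"}:
        view = view.select_families(config.families)
    X, y = view.data, _encode_labels(view.labels)
    class_counts = y.value_counts()
    if len(class_counts) < 2:
        raise ValueError("matrix must contain both classes")
    if class_counts.min() < config.folds:
        raise ValueError(
            f"smallest class has {class_counts.min()} members; "
            f"use fewer than {config.folds} folds"
        )
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True,
                          random_state=config.seed)
    rng = np.random.default_rng(config.seed)
    logger.info("crossvalidate %s/%s smote=%s folds=%d seed=%d",
                "+".join(config.families), config.algorithm, config.smote,
                config.folds, config.seed)

    oof_scores = np.full(len(y), np.nan)
    per_fold = []
    for fold_idx, (tr, te) in enumerate(skf.split(X, y)):
        X_tr, y_tr = X.iloc[tr], y.iloc[tr]
        if config.smote:
            X_tr, y_tr, donors = balance_training_fold(X_tr, y_tr, rng)
            if _donor_log is not None:
                _donor_log.append({"fold": fold_idx,
                                   "train_ids": list(X.index[tr]),
                                   "test_ids": list(X.index[te]),
                                   "donors": donors})
        pipe = make_pipeline(config.algorithm, config.seed)
        pipe.fit(X_tr, y_tr)
        proba = pipe.predict_proba(X.iloc[te])
        tox_col = list(pipe.classes_).index(1)
        scores = proba[:, tox_col]
        oof_scores[te] = scores
        pred = scores >= 0.5
        y_te = y.iloc[te].to_numpy()
        tp = int((pred & (y_te == 1)).sum())
        fp = int((pred & (y_te == 0)).sum())
        tn = int((~pred & (y_te == 0)).sum())
        fn = int((~pred & (y_te == 1)).sum())
        per_fold.append({"fold": fold_idx, "tp": tp, "fp": fp, "tn": tn, "fn": fn,
                         **compute_metrics(tp, fp, tn, fn, scores, y_te)})

    assert not np.isnan(oof_scores).any()
    y_arr = y.to_numpy()
    pred = oof_scores >= 0.5
    tp = int((pred & (y_arr == 1)).sum())
    fp = int((pred & (y_arr == 0)).sum())
    tn = int((~pred & (y_arr == 0)).sum())
    fn = int((~pred & (y_arr == 1)).sum())
    metrics = compute_metrics(tp, fp, tn, fn, oof_scores, y_arr)
    youden = youden_optimize(oof_scores, y_arr)
    return ExperimentReport(
        config=config, auc=metrics["auc"],
        sensitivity=metrics["sensitivity"], specificity=metrics["specificity"],
        accuracy=metrics["accuracy"], balanced_accuracy=metrics["balanced_accuracy"],
        f1=metrics["f1"], confusion=(tp, fp, tn, fn),
        per_fold=tuple(per_fold), youden=youden,
        oof_scores=tuple(float(s) for s in oof_scores),
        oof_labels=tuple(int(v) for v in y_arr),
    )


def enumerate_grid(folds: int = 10, seed: int = 0) -> list[ExperimentConfig]:
    """The full 7 x 4 x 2 = 56 experiment grid, in deterministic order."""
    return [ExperimentConfig(fams, alg, smote, folds, seed)
            for fams in FAMILY_COMBINATIONS
            for alg in ALGORITHMS
            for smote in (False, True)]


def run_grid(matrix: FeatureMatrix, folds: int = 10, seed: int = 0
             ) -> list[ExperimentReport]:
    """Run all 56 experiments; the best configuration is the max-AUC report."""
    reports = [crossvalidate(matrix, cfg) for cfg in enumerate_grid(folds, seed)]
    best = best_report(reports)
    logger.info("grid complete; best AUC %.3f for %s/%s smote=%s",
                best.auc, "+".join(best.config.families),
                best.config.algorithm, best.config.smote)
    return reports


def best_report(reports: Sequence[ExperimentReport]) -> ExperimentReport:
    return max(reports, key=lambda r: (r.auc if r.auc is not None else -1,))


# ---------------------------------------------------------------------------
# information gain

def _entropy(counts: np.ndarray) -> float:
    tot = counts.sum()
    if tot == 0:
        return 0.0
    p = counts[counts > 0] / tot
    return float(-(p * np.log2(p)).sum())


def expand_value_levels(matrix: FeatureMatrix) -> tuple[pd.DataFrame, dict[str, FeatureDescriptor]]:
    """Binary indicator per observed (column, value) level, named in field style."""
    view = matrix.training_view()
    cols: dict[str, np.ndarray] = {}
    descs: dict[str, FeatureDescriptor] = {}
    for col in view.data.columns:
        desc = matrix.descriptors[col]
        series = view.data[col]
        for value in sorted(series.unique()):
            name = value_level_name(desc, value)
            cols[name] = (series == value).to_numpy()
            descs[name] = FeatureDescriptor(desc.family, desc.positions, name)
    return pd.DataFrame(cols, index=view.data.index), descs


def info_gain(x: Sequence, y: Sequence[int]) -> float:
    """IG(Y; X) = H(Y) - H(Y|X), base-2 entropy over the empirical table."""
    x = np.asarray(x)
    y = np.asarray(y)
    classes = np.unique(y)
    h_y = _entropy(np.array([(y == c).sum() for c in classes]))
    h_cond = 0.0
    n = len(y)
    for v in np.unique(x):
        mask = x == v
        h_cond += mask.sum() / n * _entropy(
            np.array([(y[mask] == c).sum() for c in classes]))
    return h_y - h_cond


def info_gain_rank(matrix: FeatureMatrix, cutoff: float = 0.01
                   ) -> list[RankedFeature]:
    """Rank (column, value) level features by information gain.

    Features with IG below the cutoff are removed.  Occurrence counts the
    tox and nox sequences exhibiting the level.  Ties break by name.
    """
    view = matrix.training_view()
    y = _encode_labels(view.labels).to_numpy()
    indicators, descs = expand_value_levels(matrix)
    scored = []
    for name in indicators.columns:
        x = indicators[name].to_numpy()
        ig = info_gain(x, y)
        if ig < cutoff:
            continue
        occ = (int(x[y == 1].sum()), int(x[y == 0].sum()))
        scored.append((ig, name, descs[name], occ))
    scored.sort(key=lambda t: (-t[0], t[1]))
    per_family: dict[str, int] = {}
    ranked = []
    for g_rank, (ig, name, desc, occ) in enumerate(scored, 1):
        per_family[desc.family] = per_family.get(desc.family, 0) + 1
        ranked.append(RankedFeature(desc, ig, per_family[desc.family], g_rank, occ))
    logger.info("info-gain ranking kept %d features (cutoff %.3g)",
                len(ranked), cutoff)
    return ranked


# ---------------------------------------------------------------------------
# control experiments

def incremental_feature_experiment(matrix: FeatureMatrix,
                                   ranked: Sequence[RankedFeature],
                                   k_per_family: int = 10,
                                   algorithm: str = "random_forest",
                                   folds: int = 10, seed: int = 0
                                   ) -> list[ExperimentReport]:
    """Classifiers on nested top-feature sets (value-level indicators).

    Takes the ``k_per_family`` best features of each family, orders the
    pool by general rank and trains one cross-validated classifier per
    nested prefix — 30 classifiers when three families each contribute 10.
    """
    pool = [r for r in ranked if r.family_rank <= k_per_family]
    pool.sort(key=lambda r: r.general_rank)
    if not pool:
        raise ValueError("no ranked features to add")
    n_families = len({r.descriptor.family for r in ranked})
    if len(pool) < k_per_family * n_families:
        logger.warning("only %d ranked features available; trajectory shortened",
                       len(pool))
    view = matrix.training_view()
    indicators, descs = expand_value_levels(matrix)
    reports = []
    for k in range(1, len(pool) + 1):
        names = [r.descriptor.name for r in pool[:k]]
        sub = FeatureMatrix(
            indicators[names].astype(str), view.labels,
            {n: descs[n] for n in names})
        cfg = ExperimentConfig(tuple(dict.fromkeys(r.descriptor.family
                                                   for r in pool[:k])),
                               algorithm, False, folds, seed)
        reports.append(crossvalidate(sub, cfg, select_columns=False))
    return reports


def random_label_control(matrix: FeatureMatrix, which_class: str = "tox",
                         seed: int = 0, algorithm: str = "random_forest",
                         folds: int = 10) -> ExperimentReport:
    """Overfitting check: relabel half of one class at random and re-fit.

    All rows of ``which_class`` are taken, floor(n/2) of them are randomly
    flipped to the opposite label, and a cross-validated classifier is
    scored — any real signal is gone, so AUC should sit near 0.5.
    """
    view = matrix.training_view()
    keep = view.labels == which_class
    if keep.sum() < 2 * folds:
        raise ValueError(f"class {which_class!r} too small for {folds}-fold control")
    data = view.data.loc[keep]
    other = "nox" if which_class == "tox" else "tox"
    rng = np.random.default_rng(seed)
    n = keep.sum()
    flip = rng.choice(n, size=n // 2, replace=False)
    labels = pd.Series(which_class, index=data.index, name="label")
    labels.iloc[flip] = other
    logger.info("random-label control: flipped %d of %d %s rows (seed %d)",
                n // 2, n, which_class, seed)
    sub = FeatureMatrix(data, labels, {c: matrix.descriptors[c] for c in data.columns})
    cfg = ExperimentConfig(tuple(sub.families), algorithm, False, folds, seed)
    return crossvalidate(sub, cfg)


# ---------------------------------------------------------------------------
# trained model + prediction

@dataclass
class TrainedModel:
    """A fitted pipeline plus everything needed to score new encodings."""

    pipeline: Pipeline
    columns: tuple[str, ...]
    descriptors: dict[str, FeatureDescriptor]
    config: ExperimentConfig
    threshold: float = 0.5

    def score(self, data: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.columns if c not in data.columns]
        if missing:
            raise ValueError(f"feature universe mismatch; missing columns {missing[:5]}")
        proba = self.pipeline.predict_proba(data[list(self.columns)])
        tox_col = list(self.pipeline.classes_).index(1)
        return proba[:, tox_col]


def fit_model(matrix: FeatureMatrix, config: ExperimentConfig,
              threshold: float | None = None) -> TrainedModel:
    """Fit one final model on all labelled rows.

    When no threshold is given, the Youden-optimal cutpoint from a
    cross-validation under the same configuration is used.
    """
    if threshold is None:
        threshold = crossvalidate(matrix, config).youden[0]
    view = matrix.training_view()
    if set(config.families) != {"GLVJ"}:
        view = view.select_families(config.families)
    X, y = view.data, _encode_labels(view.labels)
    if config.smote:
        X, y, _ = balance_training_fold(X, y, np.random.default_rng(config.seed))
    pipe = make_pipeline(config.algorithm, config.seed)
    pipe.fit(X, y)
    return TrainedModel(pipe, tuple(view.data.columns),
                        {c: view.descriptors[c] for c in view.data.columns},
                        config, float(threshold))


def predict(model: TrainedModel, matrix: FeatureMatrix
            ) -> pd.DataFrame:
    """Per-sequence predicted label and tox-probability.

    A sequence is called tox when its confidence reaches the model's
    operating threshold (Youden-optimal by default).
    """
    scores = model.score(matrix.data)
    labels = np.where(scores >= model.threshold, "tox", "nox")
    return pd.DataFrame({"label": labels, "confidence": scores},
                        index=matrix.data.index)
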