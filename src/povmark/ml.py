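"""Leakage-free nested LOOCV classification with small-sample CIs.

The evaluation protocol holds out one participant per outer fold; everything
fitted — the median imputer, the recursive-feature-elimination subset, the
hyperparameters and the probability-calibration map — is a function of the
training rows only. Pooled outer-fold predictions yield confusion-count
metrics with Wilson 95% CIs, a stratified-bootstrap F1 CI, and a ROC-AUC
with the Hanley-McNeil (1982) normal-approximation CI. Gini importances are
averaged across the tree-ensemble learners for interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .datamodel import FeatureMatrix

POSITIVE_LABEL = "MDD"

#: Learners with impurity-based feature importances (eligible for the
#: averaged-importance report and usable as their own RFE ranker).
TREE_LEARNERS = ("extra_trees", "random_forest", "gradient_boosting", "adaboost")
ALL_LEARNERS = TREE_LEARNERS + ("knn", "svm")

DEFAULT_GRIDS: dict[str, list[dict]] = {
    "extra_trees": [
        {"n_estimators": n, "max_depth": d} for n in (100, 300) for d in (None, 6)
    ],
    "random_forest": [
        {"n_estimators": n, "max_depth": d} for n in (100, 300) for d in (None, 6)
    ],
    "gradient_boosting": [{"n_estimators": n} for n in (100, 300)],
    "adaboost": [{"n_estimators": n} for n in (100, 300)],
    "knn": [{"n_neighbors": k} for k in (3, 5, 7)],
    "svm": [{"C": c} for c in (0.1, 1.0, 10.0)],
}


def make_learner(name: str, seed: int = 0, **params):
    """Instantiate a registry learner with a fixed random seed."""
    if name == "extra_trees":
        return ExtraTreesClassifier(random_state=seed, **params)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if name == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **params)
    if name == "adaboost":
        return AdaBoostClassifier(random_state=seed, **params)
    if name == "knn":
        return KNeighborsClassifier(**params)
    if name == "svm":
        # raw decision-function scores; probabilities come from the pipeline's
        # own Platt/isotonic calibration stage
        return SVC(random_state=seed, **params)
    raise ValueError(f"unknown learner {name!r}; registry: {ALL_LEARNERS}")


@dataclass
class CVConfig:
    """Tunables of the nested-LOOCV protocol (all fold-internal)."""

    inner_folds: int = 5
    rfe_sizes: tuple[int, ...] = (3, 5, 8, 10, 15)
    grids: dict[str, list[dict]] | None = None
    calibration: tuple[str, ...] = ("platt", "isotonic")
    ranker_params: dict = field(default_factory=lambda: {"n_estimators": 100})

    def grid_for(self, learner: str) -> list[dict]:
        grids = self.grids if self.grids is not None else DEFAULT_GRIDS
        return grids.get(learner, [{}])


#: A light configuration for simulation studies and quick runs: two candidate
#: subset sizes, a single hyperparameter point, Platt calibration only.
def light_config() -> CVConfig:
    grids = {name: [{}] for name in ALL_LEARNERS}
    for name in ("extra_trees", "random_forest"):
        grids[name] = [{"n_estimators": 20, "max_depth": 5}]
    for name in ("gradient_boosting", "adaboost"):
        grids[name] = [{"n_estimators": 30}]
    return CVConfig(
        inner_folds=3,
        rfe_sizes=(10, 15),
        grids=grids,
        calibration=("platt",),
        ranker_params={"n_estimators": 5, "max_depth": 3},
    )


@dataclass
class FoldArtifacts:
    """Everything fitted inside one outer fold (training rows only)."""

    fold_id: str
    imputer_medians: dict[str, float]
    dropped_features: tuple[str, ...]
    selected_features: tuple[str, ...]
    hyperparameters: dict
    calibration_method: str
    calibration_brier: dict[str, float]


def fold_preprocess(
    train: pd.DataFrame, test: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float], tuple[str, ...]]:
    """Median-impute missing entries using training-fold statistics only.

    Per-feature medians are computed on the training rows and applied to both
    the training rows and the held-out row; a feature entirely missing in
    training is dropped for the fold. (All 15 behavioral features are
    continuous; a categorical covariate would take the training mode
    instead.) Returns (train, test, fitted medians, dropped features).
    """
    medians = train.median(axis=0, skipna=True)
    dropped = tuple(medians.index[medians.isna()])
    keep = [c for c in train.columns if c not in dropped]
    train_f = train[keep].fillna(medians[keep])
    test_f = test[keep].fillna(medians[keep])
    return train_f, test_f, medians[keep].to_dict(), dropped


def _rfe_subset_path(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    ranker,
    sizes: tuple[int, ...],
) -> dict[int, list[int]]:
    """Step-1 recursive elimination path, recording the surviving index set
    at each requested size (one elimination sweep, ranker refit per step)."""
    sizes = sorted({s for s in sizes if s <= len(feature_names)}, reverse=True)
    remaining = list(range(len(feature_names)))
    path: dict[int, list[int]] = {}
    if sizes and sizes[0] == len(remaining):
        path[sizes[0]] = list(remaining)
        sizes = sizes[1:]
    for target in sizes:
        while len(remaining) > target:
            ranker.fit(X[:, remaining], y)
            worst = int(np.argmin(ranker.feature_importances_))
            remaining.pop(worst)
        path[target] = list(remaining)
    return path


def _raw_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous class-1 score: a probability when the learner provides one,
    otherwise the decision function (calibration maps either to [0, 1])."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def _oof_scores(model, X: np.ndarray, y: np.ndarray, splits) -> np.ndarray:
    """Out-of-fold raw scores over precomputed inner-CV splits."""
    oof = np.empty(len(y))
    for tr, te in splits:
        fitted = clone(model).fit(X[tr], y[tr])
        oof[te] = _raw_scores(fitted, X[te])
    return oof


def _score_accuracy(oof: np.ndarray, y: np.ndarray, is_proba: bool) -> float:
    cut = 0.5 if is_proba else 0.0
    return float(((oof >= cut).astype(int) == y).mean())


class _PlattCalibrator:
    """Sigmoid (logistic) map from raw scores to calibrated probabilities."""

    def fit(self, scores: np.ndarray, y: np.ndarray):
        self.lr = LogisticRegression(C=1e6, max_iter=1000)
        self.lr.fit(scores.reshape(-1, 1), y)
        return self

    def predict(self, scores: np.ndarray) -> np.ndarray:
        return self.lr.predict_proba(np.asarray(scores).reshape(-1, 1))[:, 1]


class _IsotonicCalibrator:
    def fit(self, scores: np.ndarray, y: np.ndarray):
        self.iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
        self.iso.fit(scores, y)
        return self

    def predict(self, scores: np.ndarray) -> np.ndarray:
        return self.iso.predict(np.asarray(scores))


_CALIBRATORS = {"platt": _PlattCalibrator, "isotonic": _IsotonicCalibrator}


def nested_loocv(
    matrix: FeatureMatrix,
    learner: str = "extra_trees",
    config: CVConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[FoldArtifacts]]:
    """Nested leave-one-out cross-validation for one registry learner.

    Outer loop: each participant is held out once. Inner loop (stratified
    k-fold on the training rows only): the RFE subset size, the
    hyperparameters, and the calibration method (lowest inner Brier score;
    ties favor Platt) are selected. The final model is fit on the full
    training fold and its calibrated probability for the held-out participant
    is recorded. Fully reproducible from ``seed``.

    Returns (pooled predictions, per-fold artifacts); predictions carry one
    row per participant with the true label, the predicted label, and the
    calibrated probability of MDD.
    """
    config = config or CVConfig()
    X_df = matrix.data
    y = (matrix.labels == POSITIVE_LABEL).to_numpy().astype(int)
    ids = list(X_df.index)
    if y.sum() < 2 or (len(y) - y.sum()) < 2:
        raise ValueError("need at least 2 participants per class")

    rows = []
    artifacts: list[FoldArtifacts] = []
    for i, pid in enumerate(ids):
        train_mask = np.ones(len(ids), dtype=bool)
        train_mask[i] = False
        train_df = X_df.iloc[train_mask]
        test_df = X_df.iloc[[i]]
        y_tr = y[train_mask]

        train_f, test_f, medians, dropped = fold_preprocess(train_df, test_df)
        feat_names = list(train_f.columns)
        X_tr = train_f.to_numpy()
        X_te = test_f.to_numpy()

        fold_seed = (seed * 100003 + i) % (2**31 - 1)
        n_splits = min(config.inner_folds, int(y_tr.sum()), int((1 - y_tr).sum()))
        if n_splits < 2:
            raise ValueError(f"fold {pid}: a class is too small for inner CV")
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=fold_seed)
        splits = list(cv.split(X_tr, y_tr))

        grid = config.grid_for(learner)
        base = make_learner(learner, seed=fold_seed, **grid[0])
        is_proba = hasattr(base, "predict_proba")
        if learner in TREE_LEARNERS:
            ranker = make_learner(learner, seed=fold_seed, **config.ranker_params)
        else:
            ranker = ExtraTreesClassifier(random_state=fold_seed, **config.ranker_params)

        # RFE subset-size selection by inner-CV accuracy (base hyperparameters)
        path = _rfe_subset_path(X_tr, y_tr, feat_names, ranker, config.rfe_sizes)
        best_size, best_acc, size_oof = None, -np.inf, None
        for size in sorted(path):  # ties favor the smaller subset
            oof = _oof_scores(base, X_tr[:, path[size]], y_tr, splits)
            acc = _score_accuracy(oof, y_tr, is_proba)
            if acc > best_acc:
                best_size, best_acc, size_oof = size, acc, oof
        subset = path[best_size]
        X_sub, X_te_sub = X_tr[:, subset], X_te[:, subset]

        # hyperparameter search on the selected subset (first point's OOF
        # scores were already computed during size selection)
        best_params, best_acc, best_oof = grid[0], -np.inf, size_oof
        for k, params in enumerate(grid):
            if k == 0:
                oof = size_oof
            else:
                model = make_learner(learner, seed=fold_seed, **params)
                oof = _oof_scores(model, X_sub, y_tr, splits)
            acc = _score_accuracy(oof, y_tr, is_proba)
            if acc > best_acc:
                best_params, best_acc, best_oof = params, acc, oof

        # calibration-method choice by inner Brier score on OOF scores
        briers: dict[str, float] = {}
        calibrators = {}
        for method in config.calibration:
            cal = _CALIBRATORS[method]().fit(best_oof, y_tr)
            briers[method] = float(np.mean((cal.predict(best_oof) - y_tr) ** 2))
            calibrators[method] = cal
        # lowest Brier wins; exact ties favor Platt (fewer parameters)
        order = {m: k for k, m in enumerate(("platt", "isotonic"))}
        chosen = min(briers, key=lambda m: (briers[m], order.get(m, 9)))

        final = make_learner(learner, seed=fold_seed, **best_params)
        final.fit(X_sub, y_tr)
        raw = _raw_scores(final, X_te_sub)
        proba = float(np.clip(calibrators[chosen].predict(raw)[0], 0.0, 1.0))

        rows.append(
            {
                "participant_id": pid,
                "y_true": int(y[i]),
                "y_pred": int(proba >= 0.5),
                "proba_mdd": proba,
            }
        )
        artifacts.append(
            FoldArtifacts(
                fold_id=pid,
                imputer_medians=medians,
                dropped_features=dropped,
                selected_features=tuple(feat_names[j] for j in subset),
                hyperparameters=dict(best_params),
                calibration_method=chosen,
                calibration_brier=briers,
            )
        )
    preds = pd.DataFrame(rows).set_index("participant_id")
    return preds, artifacts


def wilson_ci(p: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    ``n`` is the effective denominator: the metric's own denominator in
    strict mode, or the full cohort size in replicate mode (the convention
    under which every proportion metric shares a common n).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("proportion must lie in [0, 1]")
    z = sps.norm.ppf(1 - (1 - conf) / 2)
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (float(max(0.0, center - half)), float(min(1.0, center + half)))


def hanley_mcneil_auc_ci(
    auc: float, n_pos: int, n_neg: int, conf: float = 0.95
) -> tuple[float, float, float]:
    """Hanley-McNeil (1982) normal-approximation CI for an ROC-AUC.

    SE^2 = [A(1-A) + (n_pos-1)(Q1-A^2) + (n_neg-1)(Q2-A^2)] / (n_pos n_neg)
    with Q1 = A/(2-A) and Q2 = 2A^2/(1+A); AUCs below 0.5 are reflected.
    Returns (lo, hi, se), interval clipped to [0, 1].
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one case per class")
    a = max(auc, 1.0 - auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a**2 / (1.0 + a)
    se2 = (a * (1 - a) + (n_pos - 1) * (q1 - a**2) + (n_neg - 1) * (q2 - a**2)) / (
        n_pos * n_neg
    )
    se = float(np.sqrt(max(0.0, se2)))
    z = sps.norm.ppf(1 - (1 - conf) / 2)
    return (float(max(0.0, auc - z * se)), float(min(1.0, auc + z * se)), se)


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, int]:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return {
        "tp": int(((y_true == 1) & (y_pred == 1)).sum()),
        "fn": int(((y_true == 1) & (y_pred == 0)).sum()),
        "tn": int(((y_true == 0) & (y_pred == 0)).sum()),
        "fp": int(((y_true == 0) & (y_pred == 1)).sum()),
    }


def metrics_from_counts(c: dict[str, int]) -> dict[str, float]:
    tp, fn, tn, fp = c["tp"], c["fn"], c["tn"], c["fp"]
    n = tp + fn + tn + fp
    return {
        "accuracy": (tp + tn) / n if n else float("nan"),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "f1": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan"),
    }


def _f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return metrics_from_counts(confusion_counts(y_true, y_pred))["f1"]


def stratified_bootstrap_f1_ci(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    B: int = 2000,
    conf: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for F1, resampling within each true class."""
    rng = np.random.default_rng(seed)
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    pos = np.flatnonzero(y_true == 1)
    neg = np.flatnonzero(y_true == 0)
    stats = np.empty(B)
    for b in range(B):
        idx = np.concatenate(
            [rng.choice(pos, size=len(pos)), rng.choice(neg, size=len(neg))]
        )
        stats[b] = _f1(y_true[idx], y_pred[idx])
    lo, hi = np.nanpercentile(stats, [(1 - conf) / 2 * 100, (1 + conf) / 2 * 100])
    return float(lo), float(hi)


def pooled_metrics(
    preds: pd.DataFrame,
    bootstrap_B: int = 2000,
    seed: int = 0,
    wilson_mode: str = "replicate",
    conf: float = 0.95,
) -> dict:
    """Full metric report from pooled outer-fold predictions.

    Proportion metrics carry Wilson CIs — replicate mode uses the total
    cohort size as the denominator for every proportion (the convention under
    which a single n is quoted for all intervals); strict mode uses each
    metric's own denominator. The F1 CI comes from a stratified bootstrap and
    the ROC-AUC CI from the Hanley-McNeil approximation.
    """
    y_true = preds["y_true"].to_numpy()
    y_pred = preds["y_pred"].to_numpy()
    proba = preds["proba_mdd"].to_numpy()
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be represented in the pooled predictions")
    counts = confusion_counts(y_true, y_pred)
    point = metrics_from_counts(counts)
    n_total = n_pos + n_neg
    strict_n = {
        "accuracy": n_total,
        "precision": counts["tp"] + counts["fp"],
        "sensitivity": n_pos,
        "specificity": n_neg,
    }
    report: dict = {"counts": counts, "n_pos": n_pos, "n_neg": n_neg,
                    "wilson_mode": wilson_mode}
    for metric in ("accuracy", "precision", "sensitivity", "specificity"):
        n_eff = n_total if wilson_mode == "replicate" else strict_n[metric]
        value = point[metric]
        ci = wilson_ci(value, max(1, n_eff), conf) if np.isfinite(value) else (np.nan, np.nan)
        report[metric] = {"value": value, "ci": ci}
    f1_ci = stratified_bootstrap_f1_ci(y_true, y_pred, B=bootstrap_B, conf=conf, seed=seed)
    report["f1"] = {"value": point["f1"], "ci": f1_ci}
    auc = float(roc_auc_score(y_true, proba))
    lo, hi, se = hanley_mcneil_auc_ci(auc, n_pos, n_neg, conf)
    report["roc_auc"] = {"value": auc, "ci": (lo, hi), "se": se}
    return report


def averaged_importance(
    matrix: FeatureMatrix,
    learners: tuple[str, ...] = TREE_LEARNERS,
    seed: int = 0,
    params: dict | None = None,
) -> pd.Series:
    """Model-averaged Gini feature importances.

    Each eligible (impurity-based) learner is fit on the median-imputed full
    matrix; its importances are normalized to sum to 1 and the unweighted
    mean across learners is returned (sums to 1). Learners without
    impurity importances are excluded.
    """
    eligible = [name for name in learners if name in TREE_LEARNERS]
    if not eligible:
        raise ValueError("no learner with impurity-based importances in the registry")
    X = matrix.data.fillna(matrix.data.median(axis=0, skipna=True))
    y = (matrix.labels == POSITIVE_LABEL).to_numpy().astype(int)
    acc = np.zeros(X.shape[1])
    for k, name in enumerate(eligible):
        model = make_learner(name, seed=seed + k, **(params or {}))
        model.fit(X.to_numpy(), y)
        imp = np.asarray(model.feature_importances_, dtype=float)
        total = imp.sum()
        acc += imp / total if total > 0 else 1.0 / len(imp)
    out = pd.Series(acc / len(eligible), index=X.columns)
    return out / out.sum()


def evaluate_classifier(
    matrix: FeatureMatrix,
    learner: str = "extra_trees",
    config: CVConfig | None = None,
    seed: int = 0,
    bootstrap_B: int = 2000,
    wilson_mode: str = "replicate",
) -> dict:
    """Nested LOOCV + pooled metrics + averaged importances for one learner."""
    preds, artifacts = nested_loocv(matrix, learner, config, seed)
    report = pooled_metrics(preds, bootstrap_B=bootstrap_B, seed=seed,
                            wilson_mode=wilson_mode)
    report["learner"] = learner
    report["importances"] = averaged_importance(matrix, seed=seed).to_dict()
    report["selected_feature_frequency"] = (
        pd.Series(
            [f for a in artifacts for f in a.selected_features]
        ).value_counts().to_dict()
    )
    return {"report": report, "predictions": preds, "artifacts": artifacts}
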