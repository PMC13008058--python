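"""Multiclass abundance classes, boosted-tree tuning, metrics, and importance.

Abundance at each site/day is binned into Low / High / VeryHigh classes by
percentile cuts of the pooled life-stage distribution (25/75 by default;
10/90 for the zero-inflated egg counts).  A gradient-boosted tree model
(xgboost engine behind a thin fit/predict-proba contract) is tuned over a
Latin-hypercube design of 30 candidates with stratified 10-fold
cross-validated macro one-vs-rest AUC, then scored by accuracy, macro AUC
and the multiclass Brier score (per-observation sum of squared probability
errors, range 0–2).  Variable importance is permutation-based: shuffle one
column, model held fixed, and record the increase in mean multiclass
cross-entropy, averaged over 50 permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "CLASS_LABELS",
    "ClassThresholds",
    "make_classes",
    "split_train_test",
    "HYPERPARAM_BOUNDS",
    "TunedModel",
    "tune_boosted_trees",
    "ClassifierMetrics",
    "multiclass_metrics",
    "ImportanceTable",
    "permutation_importance",
]

CLASS_LABELS = ("Low", "High", "VeryHigh")

# engine-documented search box for the five tuned hyperparameters
HYPERPARAM_BOUNDS = {
    "n_estimators": (50, 500),
    "min_child_weight": (1, 10),
    "max_depth": (2, 8),
    "learning_rate": (0.02, 0.3),   # sampled on log scale
    "gamma": (0.0, 5.0),            # loss reduction to split
}


@dataclass
class ClassThresholds:
    """Percentile cuts defining the three abundance classes."""

    lower_pct: float = 25.0
    upper_pct: float = 75.0
    lower_cut: float = float("nan")
    upper_cut: float = float("nan")

    def __post_init__(self):
        if not self.lower_pct < self.upper_pct:
            raise ValueError("lower_pct must be < upper_pct")


def make_classes(values, thresholds: ClassThresholds | None = None) -> tuple[pd.Categorical, ClassThresholds]:
    """Label abundances Low (< lower cut), High ([lower, upper]), VeryHigh (> upper).

    Cuts are percentiles of the pooled distribution.  A degenerate
    distribution where both cuts coincide cannot support three classes and
    raises, reporting the tied mass.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise ValueError("need at least 10 abundance values")
    t = thresholds or ClassThresholds()
    lo, hi = np.percentile(values, [t.lower_pct, t.upper_pct])
    if lo == hi:
        tie = np.mean(values == lo)
        raise ValueError(
            f"degenerate class cuts: {t.lower_pct}th and {t.upper_pct}th percentile "
            f"both {lo} ({tie:.0%} of values tied there)"
        )
    t.lower_cut, t.upper_cut = float(lo), float(hi)
    labels = np.where(values < lo, "Low", np.where(values > hi, "VeryHigh", "High"))
    return pd.Categorical(labels, categories=list(CLASS_LABELS), ordered=True), t


def split_train_test(X: pd.DataFrame, y, fraction: float = 0.75, seed: int = 0):
    """Class-stratified random split; deterministic given seed."""
    if len(X) < 8:
        raise ValueError("need at least 8 rows to split")
    if fraction >= 1.0:
        import warnings

        warnings.warn("test fraction is 0; returning an empty test set", stacklevel=2)
        return X, X.iloc[0:0], np.asarray(y), np.asarray(y)[:0]
    Xtr, Xte, ytr, yte = train_test_split(
        X, np.asarray(y), train_size=fraction, stratify=np.asarray(y), random_state=seed
    )
    if len(np.unique(ytr)) < len(np.unique(np.asarray(y))):
        raise ValueError("a class is absent from the training partition")
    return Xtr, Xte, ytr, yte


@dataclass
class TunedModel:
    model: object
    params: dict
    cv_auc: float
    candidates: pd.DataFrame
    classes_: np.ndarray = field(default=None)

    def predict_proba(self, X) -> np.ndarray:
        return self.model.predict_proba(X)


def _lhs_candidates(n: int, seed: int) -> list[dict]:
    sampler = qmc.LatinHypercube(d=5, seed=seed)
    u = sampler.random(n)
    cands = []
    for row in u:
        lr_lo, lr_hi = HYPERPARAM_BOUNDS["learning_rate"]
        ne = HYPERPARAM_BOUNDS["n_estimators"]
        mcw = HYPERPARAM_BOUNDS["min_child_weight"]
        dep = HYPERPARAM_BOUNDS["max_depth"]
        cands.append({
            "n_estimators": int(round(ne[0] + row[0] * (ne[1] - ne[0]))),
            "min_child_weight": int(round(mcw[0] + row[1] * (mcw[1] - mcw[0]))),
            "max_depth": int(round(dep[0] + row[2] * (dep[1] - dep[0]))),
            "learning_rate": float(np.exp(np.log(lr_lo) + row[3] * (np.log(lr_hi) - np.log(lr_lo)))),
            "gamma": float(row[4] * HYPERPARAM_BOUNDS["gamma"][1]),
        })
    return cands


def _new_engine(params: dict, seed: int):
    from xgboost import XGBClassifier

    return XGBClassifier(
        objective="multi:softprob",
        eval_metric="mlogloss",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        **params,
    )


def tune_boosted_trees(
    Xtr: pd.DataFrame,
    ytr,
    n_candidates: int = 30,
    folds: int = 10,
    seed: int = 0,
) -> TunedModel:
    """Latin-hypercube tuning of the boosted-tree engine by CV macro AUC.

    ``folds`` stratified folds per candidate; the winner (max mean AUC) is
    refit on the full training partition.
    """
    y = pd.Categorical(ytr, categories=list(CLASS_LABELS))
    if y.isna().any():
        y = pd.Categorical(ytr)
    codes = y.codes
    if len(np.unique(codes)) < 2:
        raise ValueError("training data needs at least two classes")
    cands = _lhs_candidates(n_candidates, seed)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = []
    for k, params in enumerate(cands):
        aucs = []
        for tr_idx, va_idx in skf.split(Xtr, codes):
            eng = _new_engine(params, seed)
            eng.fit(Xtr.iloc[tr_idx], codes[tr_idx])
            proba = eng.predict_proba(Xtr.iloc[va_idx])
            aucs.append(_macro_ovr_auc(codes[va_idx], proba, n_classes=proba.shape[1]))
        rows.append({**params, "cv_auc": float(np.mean(aucs)), "candidate": k})
    table = pd.DataFrame(rows)
    best = table.loc[table["cv_auc"].idxmax()]
    params = {k: best[k] for k in HYPERPARAM_BOUNDS}
    params["n_estimators"] = int(params["n_estimators"])
    params["min_child_weight"] = int(params["min_child_weight"])
    params["max_depth"] = int(params["max_depth"])
    model = _new_engine(params, seed)
    model.fit(Xtr, codes)
    return TunedModel(
        model=model, params=params, cv_auc=float(best["cv_auc"]),
        candidates=table, classes_=np.asarray(y.categories),
    )


def _macro_ovr_auc(y_codes, proba, n_classes=None) -> float:
    """Unweighted mean of one-vs-rest AUCs; classes absent from y are skipped."""
    n_classes = n_classes or proba.shape[1]
    aucs = []
    for c in range(n_classes):
        mask = y_codes == c
        if mask.all() or not mask.any():
            continue
        aucs.append(roc_auc_score(mask.astype(int), proba[:, c]))
    return float(np.mean(aucs))


@dataclass
class ClassifierMetrics:
    accuracy: float
    macro_auc: float
    brier: float
    per_class_auc: dict

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "macro_auc": self.macro_auc,
            "brier": self.brier, "per_class_auc": self.per_class_auc,
        }


def multiclass_metrics(proba: np.ndarray, y_codes) -> ClassifierMetrics:
    """Accuracy (argmax), macro one-vs-rest AUC, and multiclass Brier score.

    Brier is the mean over observations of the summed squared difference
    between predicted class probabilities and the one-hot outcome (0–2).
    """
    proba = np.asarray(proba, dtype=float)
    y_codes = np.asarray(y_codes)
    if np.any(np.abs(proba.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1")
    acc = float((proba.argmax(axis=1) == y_codes).mean())
    onehot = np.zeros_like(proba)
    onehot[np.arange(len(y_codes)), y_codes] = 1.0
    brier = float(((proba - onehot) ** 2).sum(axis=1).mean())
    per_class = {}
    for c in range(proba.shape[1]):
        mask = (y_codes == c).astype(int)
        if 0 < mask.sum() < len(mask):
            per_class[c] = float(roc_auc_score(mask, proba[:, c]))
    return ClassifierMetrics(
        accuracy=acc, macro_auc=float(np.mean(list(per_class.values()))),
        brier=brier, per_class_auc=per_class,
    )


def _cross_entropy(proba, y_codes) -> float:
    p_true = proba[np.arange(len(y_codes)), y_codes]
    return float(-np.mean(np.log(np.clip(p_true, 1e-15, None))))


@dataclass
class ImportanceTable:
    table: pd.DataFrame  # variable, delta_loss, se, rank

    def top(self, k: int, exclude: tuple[str, ...] = ()) -> list[str]:
        t = self.table[~self.table["variable"].isin(exclude)]
        return t.sort_values("rank")["variable"].head(k).tolist()


def permutation_importance(
    model, X: pd.DataFrame, y_codes, n_perm: int = 50, seed: int = 0
) -> ImportanceTable:
    """Permutation importance under multiclass cross-entropy loss.

    For each variable, its column is shuffled (model unchanged) and the
    increase of −mean log p(true class) over the baseline is recorded,
    averaged over ``n_perm`` permutations; variables are ranked by the mean
    increase, descending.  ``se`` is the Monte-Carlo standard error of the
    mean increase across permutations.
    """
    rng = np.random.default_rng(seed)
    y_codes = np.asarray(y_codes)
    baseline = _cross_entropy(model.predict_proba(X), y_codes)
    rows = []
    for col in X.columns:
        deltas = np.empty(n_perm)
        Xp = X.copy()
        for i in range(n_perm):
            Xp[col] = rng.permutation(X[col].to_numpy())
            deltas[i] = _cross_entropy(model.predict_proba(Xp), y_codes) - baseline
        rows.append({
            "variable": col,
            "delta_loss": float(deltas.mean()),
            "se": float(deltas.std(ddof=1) / np.sqrt(n_perm)) if n_perm > 1 else 0.0,
        })
    table = pd.DataFrame(rows)
    table["rank"] = table["delta_loss"].rank(ascending=False, method="first").astype(int)
    return ImportanceTable(table=table.sort_values("rank").reset_index(drop=True))
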