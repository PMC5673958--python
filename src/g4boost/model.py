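"""Gradient-boosted regression of G4 mismatch levels and the derived
stable/non-forming classification.

The learner is an xgboost tree ensemble regressing mm% on the sequence
features.  Five parameters define an architecture: number of trees,
interaction depth (branching points per tree), minimum child weight,
learning rate (shrinkage) and bag fraction (row subsampling).  An
architecture is scored by the mean RMSE over a twice-repeated 3-fold
cross-validation (six train/internal-test rounds); the best
architecture is retrained on the full training set, without
cross-validation, to give the final model.  The published operating
point for calling a PQS a stable G4 is a score of at least 19.1 mm%.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.stats import spearmanr

from .features import ScalingParams, apply_scaler, fit_scaler

TARGET_COLUMN = "mm"
DEFAULT_THRESHOLD = 19.1  # mm%; published operating point

_META_COLUMNS = ["seq_name", "start", "end", "strand"]  # tolerated non-features


@dataclass(frozen=True)
class GBMConfig:
    """One gradient-boosting architecture.

    Defaults are the optimum found on the genome-scale data: 2500 trees
    of interaction depth 14, minimum child weight 65, shrinkage 0.01
    and bag fraction 0.6.
    """

    n_trees: int = 2500
    interaction_depth: int = 14
    min_child_weight: float = 65.0
    learning_rate: float = 0.01
    bag_fraction: float = 0.6

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.interaction_depth < 1:
            raise ValueError("n_trees and interaction_depth must be positive")
        if self.min_child_weight <= 0:
            raise ValueError("min_child_weight must be positive")
        if not (0 < self.learning_rate <= 1) or not (0 < self.bag_fraction <= 1):
            raise ValueError("learning_rate and bag_fraction must be in (0, 1]")

    def make_regressor(self, seed: int = 0) -> xgb.XGBRegressor:
        return xgb.XGBRegressor(
            n_estimators=self.n_trees,
            max_depth=self.interaction_depth,
            min_child_weight=self.min_child_weight,
            learning_rate=self.learning_rate,
            subsample=self.bag_fraction,
            objective="reg:squarederror",
            tree_method="hist",
            n_jobs=1,
            random_state=int(seed) % (2**31),
        )


def default_grid() -> list[GBMConfig]:
    """A 32-configuration grid bracketing the genome-scale optimum.

    This is the full-size search; expect hours of CPU on large data.
    """
    grid = []
    for n_trees in (1500, 2500):
        for depth in (10, 14):
            for mcw in (25.0, 65.0):
                for lr in (0.01, 0.05):
                    for bag in (0.6, 0.8):
                        grid.append(GBMConfig(n_trees, depth, mcw, lr, bag))
    return grid


def small_grid() -> list[GBMConfig]:
    """A scaled-down 4-configuration analogue for desk-scale datasets
    (fewer, shallower trees at a higher learning rate)."""
    return [
        GBMConfig(200, 4, 10.0, 0.1, 0.6),
        GBMConfig(400, 4, 10.0, 0.1, 0.6),
        GBMConfig(200, 6, 10.0, 0.1, 0.6),
        GBMConfig(400, 6, 10.0, 0.1, 0.6),
    ]


def _split_xy(dataset: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    if TARGET_COLUMN not in dataset.columns:
        raise ValueError(f"dataset lacks the {TARGET_COLUMN!r} target column")
    feats = [c for c in dataset.columns if c != TARGET_COLUMN and c not in _META_COLUMNS]
    return dataset[feats], dataset[TARGET_COLUMN].to_numpy(dtype=float)


def split_train_test(
    dataset: pd.DataFrame, train_frac: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random, seed-reproducible partition into training and pure-test
    sets (disjoint and exhaustive)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(dataset))
    n_train = int(round(train_frac * len(dataset)))
    train = dataset.iloc[perm[:n_train]]
    test = dataset.iloc[perm[n_train:]]
    return train, test


@dataclass
class CVResult:
    """Mean RMSE of one architecture over repeats x folds rounds."""

    config: GBMConfig
    rmses: list[float]
    seed: int

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.rmses))

    def to_dict(self) -> dict:
        return {
            **asdict(self.config),
            "rmses": list(self.rmses),
            "mean_rmse": self.mean_rmse,
            "seed": self.seed,
        }


def _rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def repeated_cv(
    train: pd.DataFrame,
    config: GBMConfig,
    repeats: int = 2,
    folds: int = 3,
    seed: int = 0,
) -> CVResult:
    """Repeated k-fold cross-validation of one architecture.

    Per repeat the training rows are reshuffled and split into
    ``folds`` near-equal partitions; each partition serves once as the
    internal test while the others train.  The scaler is refit on each
    round's training portion.  Returns all repeats*folds round RMSEs
    (six for the default 2x3 design) and their mean.
    """
    if len(train) < folds:
        raise ValueError("fewer training rows than folds")
    X, y = _split_xy(train)
    rng = np.random.default_rng(seed)
    rmses: list[float] = []
    for rep in range(repeats):
        perm = rng.permutation(len(X))
        parts = np.array_split(perm, folds)
        for k in range(folds):
            test_idx = parts[k]
            train_idx = np.concatenate([parts[j] for j in range(folds) if j != k])
            scaler = fit_scaler(X.iloc[train_idx])
            Xtr = apply_scaler(scaler, X.iloc[train_idx])
            Xte = apply_scaler(scaler, X.iloc[test_idx])
            reg = config.make_regressor(seed=int(rng.integers(2**31)))
            reg.fit(Xtr, y[train_idx])
            rmses.append(_rmse(y[test_idx], reg.predict(Xte)))
    return CVResult(config=config, rmses=rmses, seed=seed)


def grid_search(
    train: pd.DataFrame,
    configs: Sequence[GBMConfig],
    repeats: int = 2,
    folds: int = 3,
    seed: int = 0,
) -> tuple[list[CVResult], GBMConfig]:
    """Cross-validate every architecture and pick the minimum-mean-RMSE
    one (ties break to the earlier config in the list)."""
    if not configs:
        raise ValueError("empty configuration grid")
    results = [
        repeated_cv(train, cfg, repeats=repeats, folds=folds, seed=seed)
        for cfg in configs
    ]
    best = min(range(len(results)), key=lambda i: results[i].mean_rmse)
    ranked = sorted(results, key=lambda r: r.mean_rmse)
    return ranked, results[best].config


def cv_report(results: Sequence[CVResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


@dataclass
class TrainedModel:
    """The fitted ensemble plus everything needed to score new PQSs:
    scaler, ordered feature list, architecture and mm% threshold."""

    booster: xgb.Booster
    scaler: ScalingParams
    feature_names: list[str]
    config: GBMConfig
    threshold: float = DEFAULT_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_names != self.scaler.feature_names:
            raise ValueError("feature list does not match scaler parameters")
        if not (0 <= self.threshold <= 100):
            raise ValueError("threshold must be an mm% in [0, 100]")

    def save(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        self.booster.save_model(os.path.join(directory, "ensemble.json"))
        self.scaler.save(os.path.join(directory, "scaler.tsv"))
        meta = {
            "feature_names": self.feature_names,
            "config": asdict(self.config),
            "threshold": self.threshold,
            "seed": self.seed,
        }
        with open(os.path.join(directory, "meta.json"), "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, directory) -> "TrainedModel":
        with open(os.path.join(directory, "meta.json")) as fh:
            meta = json.load(fh)
        booster = xgb.Booster()
        booster.load_model(os.path.join(directory, "ensemble.json"))
        return cls(
            booster=booster,
            scaler=ScalingParams.load(os.path.join(directory, "scaler.tsv")),
            feature_names=meta["feature_names"],
            config=GBMConfig(**meta["config"]),
            threshold=meta["threshold"],
            seed=meta.get("seed", 0),
        )


def train_final(
    train: pd.DataFrame,
    config: GBMConfig,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = 0,
) -> TrainedModel:
    """Train on the complete training set (no cross-validation cycles)
    with the chosen architecture; the scaler is fit on these rows
    only."""
    X, y = _split_xy(train)
    scaler = fit_scaler(X)
    reg = config.make_regressor(seed=seed)
    reg.fit(apply_scaler(scaler, X), y)
    return TrainedModel(
        booster=reg.get_booster(),
        scaler=scaler,
        feature_names=list(X.columns),
        config=config,
        threshold=threshold,
        seed=seed,
    )


def predict(model: TrainedModel, features: pd.DataFrame) -> np.ndarray:
    """Sequence-only stability scores on the mm% scale, one per input
    row, order-preserving."""
    missing = [f for f in model.feature_names if f not in features.columns]
    if missing:
        raise KeyError(f"missing features: {missing}")
    X = apply_scaler(model.scaler, features[model.feature_names])
    scores = model.booster.predict(xgb.DMatrix(X)).astype(float)
    if not np.isfinite(scores).all():
        raise RuntimeError("non-finite prediction scores")
    return scores


# ---------------------------------------------------------------------------
# Classification at an mm% threshold


@dataclass(frozen=True)
class ConfusionMetrics:
    """Rates (fractions in [0, 1]) of the stable-G4 classification;
    a metric whose denominator class is empty is None, never a silent
    NaN."""

    tpr: Optional[float]
    tnr: Optional[float]
    fpr: Optional[float]
    fdr: Optional[float]
    tp: int
    fn: int
    tn: int
    fp: int

    def as_percent(self) -> dict:
        return {
            k: (None if v is None else 100.0 * v)
            for k, v in
            {"TPR": self.tpr, "TNR": self.tnr, "FPR": self.fpr, "FDR": self.fdr}.items()
        }


def confusion_metrics(
    true_labels: np.ndarray, predicted_labels: np.ndarray
) -> ConfusionMetrics:
    """TPR, TNR, FPR and FDR with positives = stable G4.

    TPR = TP/(TP+FN), TNR = TN/(TN+FP), FPR = FP/(FP+TN),
    FDR = FP/(FP+TP).
    """
    t = np.asarray(true_labels, dtype=bool)
    p = np.asarray(predicted_labels, dtype=bool)
    if t.shape != p.shape:
        raise ValueError("label arrays differ in shape")
    tp = int(np.sum(t & p))
    fn = int(np.sum(t & ~p))
    tn = int(np.sum(~t & ~p))
    fp = int(np.sum(~t & p))

    def _rate(num: int, den: int) -> Optional[float]:
        return num / den if den else None

    return ConfusionMetrics(
        tpr=_rate(tp, tp + fn),
        tnr=_rate(tn, tn + fp),
        fpr=_rate(fp, fp + tn),
        fdr=_rate(fp, fp + tp),
        tp=tp, fn=fn, tn=tn, fp=fp,
    )


def choose_threshold(
    scores: np.ndarray,
    mm_values: np.ndarray,
    candidates: Optional[np.ndarray] = None,
) -> float:
    """Pick the mm% threshold maximising min(TPR, TNR).

    Ground truth at each candidate t is ``mm >= t`` and the prediction
    is ``score >= t`` (a single threshold dichotomises both axes).
    Ties go to the lowest threshold.  Candidates where either class is
    empty are skipped; if every candidate degenerates, raises.
    """
    scores = np.asarray(scores, dtype=float)
    mm_values = np.asarray(mm_values, dtype=float)
    if candidates is None:
        candidates = np.round(np.arange(2.0, 60.0 + 1e-9, 0.1), 1)
    best_t: Optional[float] = None
    best_obj = -math.inf
    for t in candidates:
        truth = mm_values >= t
        if truth.all() or not truth.any():
            continue
        m = confusion_metrics(truth, scores >= t)
        obj = min(m.tpr, m.tnr)
        if obj > best_obj:  # strict: ties keep the lower threshold
            best_obj, best_t = obj, float(t)
    if best_t is None:
        raise ValueError("all candidate thresholds give a one-class truth")
    return best_t


# ---------------------------------------------------------------------------
# Feature importance


def importance_report(
    model: TrainedModel,
    train: pd.DataFrame,
    directionality_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Relative feature importance with a crude directionality mark.

    Importance is the ensemble's total split gain (split counts
    weighted by squared fit improvement), normalised so the most
    influential feature scores 1; features never split on score 0.
    Directionality is the sign of the Spearman correlation between the
    raw feature and mm% on the training data — "+" stabilising, "-"
    destabilising, "*" when |rho| falls below the cutoff (a declared
    approximation to the full conditional analysis).
    """
    gains = model.booster.get_score(importance_type="total_gain")
    imp = np.array([gains.get(f, 0.0) for f in model.feature_names], dtype=float)
    top = imp.max()
    if top > 0:
        imp = imp / top
    X, y = _split_xy(train)
    marks = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns -> undefined rho
        for f in model.feature_names:
            rho = spearmanr(X[f].to_numpy(), y).statistic
            if not np.isfinite(rho) or abs(rho) < directionality_cutoff:
                marks.append("*")
            else:
                marks.append("+" if rho > 0 else "-")
    report = pd.DataFrame(
        {"feature": model.feature_names, "importance": imp, "direction": marks}
    )
    return report.sort_values(
        "importance", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
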