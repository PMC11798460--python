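"""Metrics and the leakage-safe evaluation protocol.

Classification metrics follow the standard confusion-matrix definitions with
class 1 as positive: accuracy = (TP+TN)/n, precision = TP/(TP+FP),
recall = TP/(TP+FN), F1 = harmonic mean of precision and recall.
Zero-denominator cases return 0 with a flag so reports are always complete.
Regression errors are MAE, MSE and RMSE = √MSE.

The protocol splits **before** balancing: regions (not rows) are assigned to
train and test so temporal windows never straddle the split, preprocessing
statistics are fitted on the training side only, ADASYN runs on the training
windows only, and the held-out rows stay bit-identical. k-fold
cross-validation repeats the same discipline inside every fold. A structural
leakage audit (region-disjointness, untouched held-out rows) runs on every
split.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import preprocess as prep
from .balance import AdasynConfig, AdasynResult, adasyn_balance
from .features import FeatureConfig, FeatureReport, feature_engineering
from .nets import (
    BiGRUClassifier,
    CNNClassifier,
    TrainConfig,
    ensemble_predict,
    ensemble_regress,
    train_member,
)
from .panel import LABEL_COLUMN, YIELD_COLUMN, CropPanel
from .windows import WindowSet, build_windows, select_feature_columns, unflatten

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


class LeakageError(AssertionError):
    """The structural leakage audit failed."""


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def confusion(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise EvaluationError("y_true and y_pred lengths differ")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise EvaluationError("binary 0/1 labels expected")
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def classification_metrics(c: ConfusionCounts) -> dict:
    """Accuracy/precision/recall/F1 with zero-denominator flags."""
    flags = []

    def safe(num, den, name):
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    accuracy = safe(c.TP + c.TN, c.n, "accuracy")
    precision = safe(c.TP, c.TP + c.FP, "precision")
    recall = safe(c.TP, c.TP + c.FN, "recall")
    f1 = safe(2 * precision * recall, precision + recall, "f1")
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "zero_denominator": flags,
    }


def regression_metrics(y_true, y_hat) -> dict:
    y_true = np.asarray(y_true, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y_true.shape != y_hat.shape:
        raise EvaluationError("y_true and y_hat lengths differ")
    if y_true.size == 0:
        raise EvaluationError("empty input")
    err = y_true - y_hat
    mse = float(np.mean(err**2))
    return {"mae": float(np.mean(np.abs(err))), "mse": mse, "rmse": float(np.sqrt(mse))}


# ---------------------------------------------------------------------------
# Pipeline configuration and per-split runner
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    window: int = 4
    adasyn: AdasynConfig = field(default_factory=AdasynConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    gru_hidden: int = 16
    cnn_dense: int = 16
    regression: bool = False

    def reseeded(self, seed: int) -> "PipelineConfig":
        """Copy with all stage sub-seeds derived from one global seed."""
        import copy

        cfg = copy.deepcopy(self)
        cfg.adasyn.seed = (seed * 7919 + 1) % (2**31)
        cfg.features.seed = (seed * 7919 + 2) % (2**31)
        cfg.train.seed = (seed * 7919 + 3) % (2**31)
        return cfg

    def config_hash(self) -> str:
        payload = {
            "window": self.window,
            "adasyn": vars(self.adasyn),
            "features": vars(self.features),
            "train": vars(self.train),
            "gru_hidden": self.gru_hidden,
            "cnn_dense": self.cnn_dense,
            "regression": self.regression,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


@dataclass
class EvaluationReport:
    confusion: ConfusionCounts
    metrics: dict
    member_metrics: list[dict]
    regression: dict | None
    seed: int
    config_hash: str
    n_test: int

    def to_json(self) -> str:
        payload = dict(self.__dict__)
        payload["confusion"] = vars(self.confusion)
        return json.dumps(payload, indent=2)

    def to_text(self) -> str:
        c, m = self.confusion, self.metrics
        lines = [
            f"n={self.n_test}  TP={c.TP} FP={c.FP} FN={c.FN} TN={c.TN}",
            f"accuracy={m['accuracy']:.4f} precision={m['precision']:.4f} "
            f"recall={m['recall']:.4f} f1={m['f1']:.4f}",
        ]
        for i, mm in enumerate(self.member_metrics):
            lines.append(f"member[{i}] accuracy={mm['accuracy']:.4f}")
        if self.regression:
            r = self.regression
            lines.append(f"MAE={r['mae']:.4f} MSE={r['mse']:.4f} RMSE={r['rmse']:.4f}")
        return "\n".join(lines)


@dataclass
class SplitResult:
    """Everything the training side may see, plus the untouched test panel."""

    train_panel: CropPanel
    test_panel: CropPanel
    params: prep.PreprocessParams
    train_windows: WindowSet  # transformed, pre-balance
    X_balanced: np.ndarray  # flattened balanced training windows
    y_balanced: np.ndarray
    t_balanced: np.ndarray  # window-end time of every balanced row
    adasyn: AdasynResult
    test_hash: str


def _panel_hash(panel: CropPanel) -> str:
    csv = panel.df.to_csv(index=False).encode()
    return hashlib.sha256(csv).hexdigest()


def split_regions(panel: CropPanel, test_fraction: float, seed: int, max_attempts: int = 10):
    """Region-grouped split; redraws (new sub-seed) until both sides hold
    both classes."""
    if not (0.0 < test_fraction < 1.0):
        raise EvaluationError("test_fraction must be in (0, 1)")
    regions = np.asarray(sorted(panel.df["region_id"].unique()))
    n_test = max(1, int(round(test_fraction * len(regions))))
    if n_test >= len(regions):
        raise EvaluationError("test fraction leaves no training regions")
    labels = panel.df[LABEL_COLUMN].to_numpy()
    for attempt in range(max_attempts):
        rng = np.random.default_rng((seed + attempt * 104729) % (2**31))
        perm = rng.permutation(regions)
        test_regions = set(perm[:n_test])
        in_test = panel.df["region_id"].isin(test_regions).to_numpy()
        if len(np.unique(labels[in_test])) == 2 and len(np.unique(labels[~in_test])) == 2:
            return sorted(set(regions) - test_regions), sorted(test_regions)
    raise EvaluationError("could not draw a split with both classes on both sides")


def split_then_balance(
    panel: CropPanel,
    test_fraction: float = 0.2,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> SplitResult:
    """Split by region groups, then preprocess and ADASYN-balance the
    training side only. The test panel is returned untouched (its hash is
    recorded so callers can audit bit-identity)."""
    config = config or PipelineConfig()
    if not panel.has_labels:
        raise EvaluationError("panel has no labels")
    train_regions, test_regions = split_regions(panel, test_fraction, seed)
    train_panel = CropPanel(
        panel.df[panel.df["region_id"].isin(train_regions)].reset_index(drop=True),
        list(panel.numeric_features),
        list(panel.categorical_features),
    )
    test_panel = CropPanel(
        panel.df[panel.df["region_id"].isin(test_regions)].reset_index(drop=True),
        list(panel.numeric_features),
        list(panel.categorical_features),
    )
    test_hash = _panel_hash(test_panel)

    params = prep.fit_preprocess(train_panel)
    train_t = prep.transform(train_panel, params)
    tw = build_windows(train_t, config.window)
    result = adasyn_balance(tw.flat, tw.y, config.adasyn)
    t_balanced = np.concatenate(
        [tw.t_end, np.array([tw.t_end[p] for p, _, _ in result.provenance], dtype=int)]
    )

    if _panel_hash(test_panel) != test_hash:
        raise LeakageError("test panel changed across the balance step")
    return SplitResult(
        train_panel=train_panel,
        test_panel=test_panel,
        params=params,
        train_windows=tw,
        X_balanced=result.X_balanced,
        y_balanced=result.y_balanced,
        t_balanced=t_balanced,
        adasyn=result,
        test_hash=test_hash,
    )


@dataclass
class FitResult:
    report: EvaluationReport
    feature_report: FeatureReport
    models: list
    split: SplitResult


def fit_and_evaluate(split: SplitResult, config: PipelineConfig, seed: int = 0) -> FitResult:
    """Feature engineering, member training and held-out evaluation.

    Feature engineering sees the window-end (most recent step) slice of the
    balanced training windows, so importances, NGD and ranks refer to the
    original preprocessed features; the sequence members then train on the
    balanced windows restricted to the kept features.
    """
    tw = split.train_windows
    L, F = tw.X.shape[1], tw.X.shape[2]
    balanced_windows = unflatten(split.X_balanced, L, F)
    window_end = balanced_windows[:, -1, :]

    freport = feature_engineering(
        window_end,
        split.y_balanced,
        feature_names=tw.feature_columns,
        config=config.features,
        timestamps=split.t_balanced,
    )
    kept = freport.kept if freport.kept else list(tw.feature_columns)
    kept_idx = [tw.feature_columns.index(c) for c in kept]
    X_train = balanced_windows[:, :, kept_idx]

    audit_leakage(split)

    gru = BiGRUClassifier(len(kept), hidden=config.gru_hidden, seed=config.train.seed)
    cnn = CNNClassifier(len(kept), window=L, dense=config.cnn_dense, seed=config.train.seed + 1)
    for member in (gru, cnn):
        train_member(member, X_train, split.y_balanced, config.train)

    test_t = prep.transform(split.test_panel, split.params)
    test_w = select_feature_columns(build_windows(test_t, config.window), kept)

    predictions = ensemble_predict([gru, cnn], test_w.X)
    y_pred = np.array([p.label for p in predictions])
    counts = confusion(test_w.y, y_pred)
    member_metrics = [
        classification_metrics(confusion(test_w.y, m.predict(test_w.X))) for m in (gru, cnn)
    ]

    regression = None
    if config.regression:
        regression = _regression_route(split, X_train, test_w, config, L)

    report = EvaluationReport(
        confusion=counts,
        metrics=classification_metrics(counts),
        member_metrics=member_metrics,
        regression=regression,
        seed=seed,
        config_hash=config.config_hash(),
        n_test=counts.n,
    )
    return FitResult(report=report, feature_report=freport, models=[gru, cnn], split=split)


def _regression_route(split: SplitResult, X_train: np.ndarray, test_w: WindowSet,
                      config: PipelineConfig, L: int) -> dict:
    """Train regression-head members on min-max-scaled yield; member-mean
    fusion; errors reported on the scaled axis."""
    tw = split.train_windows
    y_min, y_max = float(tw.yields.min()), float(tw.yields.max())
    span = (y_max - y_min) or 1.0
    # synthetic rows inherit no yield; train the regression heads on the
    # original (pre-balance) windows — regression has no class imbalance
    kept_idx = [tw.feature_columns.index(c) for c in test_w.feature_columns]
    X_orig = tw.X[:, :, kept_idx]
    y_scaled = (tw.yields - y_min) / span
    reg_cfg = TrainConfig(
        epochs=config.train.epochs, lr=config.train.lr, batch_size=config.train.batch_size,
        seed=config.train.seed + 11, loss="mse",
    )
    gru = BiGRUClassifier(len(kept_idx), hidden=config.gru_hidden, n_out=1, seed=reg_cfg.seed)
    cnn = CNNClassifier(len(kept_idx), window=L, dense=config.cnn_dense, n_out=1,
                        seed=reg_cfg.seed + 1)
    for member in (gru, cnn):
        train_member(member, X_orig, y_scaled, reg_cfg)
    y_hat = ensemble_regress([gru, cnn], test_w.X)
    y_true = (test_w.yields - y_min) / span
    return regression_metrics(y_true, y_hat)


def run_experiment(panel: CropPanel, config: PipelineConfig | None = None,
                   test_fraction: float = 0.2, seed: int = 0) -> FitResult:
    """split → balance → feature engineering → train → evaluate."""
    config = (config or PipelineConfig()).reseeded(seed)
    split = split_then_balance(panel, test_fraction, config, seed)
    return fit_and_evaluate(split, config, seed)


# ---------------------------------------------------------------------------
# Leakage audit
# ---------------------------------------------------------------------------


def audit_leakage(split: SplitResult) -> None:
    """Structural checks that no held-out information reached training.

    * train and test region sets are disjoint;
    * the test panel is bit-identical to the rows drawn at split time;
    * every ADASYN provenance parent/neighbor indexes a training window.
    """
    train_regions = set(split.train_panel.df["region_id"])
    test_regions = set(split.test_panel.df["region_id"])
    if train_regions & test_regions:
        raise LeakageError(f"regions on both sides: {sorted(train_regions & test_regions)}")
    if _panel_hash(split.test_panel) != split.test_hash:
        raise LeakageError("test panel mutated since the split")
    n_train = len(split.train_windows)
    for parent, neighbor, _ in split.adasyn.provenance:
        if not (0 <= parent < n_train and 0 <= neighbor < n_train):
            raise LeakageError("synthetic row derived from a non-training window")


# ---------------------------------------------------------------------------
# k-fold cross-validation
# ---------------------------------------------------------------------------


def kfold_cv(panel: CropPanel, config: PipelineConfig | None = None,
             k: int = 5, seed: int = 0) -> list[FitResult]:
    """Region-grouped k-fold CV with balancing inside each training fold."""
    config = config or PipelineConfig()
    if k < 2:
        raise EvaluationError("k must be >= 2")
    regions = np.asarray(sorted(panel.df["region_id"].unique()))
    if len(regions) < k:
        raise EvaluationError("fewer regions than folds")
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(regions), k)
    results = []
    for fold_id, held in enumerate(folds):
        held = set(held)
        in_val = panel.df["region_id"].isin(held).to_numpy()
        val_df = panel.df[in_val].reset_index(drop=True)
        train_df = panel.df[~in_val].reset_index(drop=True)
        for name, part in (("validation", val_df), ("training", train_df)):
            if part[LABEL_COLUMN].nunique() < 2:
                raise EvaluationError(f"fold {fold_id}: {name} side lacks a class")
        fold_cfg = config.reseeded(seed * 1000 + fold_id)
        train_panel = CropPanel(train_df, list(panel.numeric_features),
                                list(panel.categorical_features))
        val_panel = CropPanel(val_df, list(panel.numeric_features),
                              list(panel.categorical_features))
        split = _split_from_panels(train_panel, val_panel, fold_cfg)
        results.append(fit_and_evaluate(split, fold_cfg, seed))
    return results


def _split_from_panels(train_panel: CropPanel, test_panel: CropPanel,
                       config: PipelineConfig) -> SplitResult:
    test_hash = _panel_hash(test_panel)
    params = prep.fit_preprocess(train_panel)
    train_t = prep.transform(train_panel, params)
    tw = build_windows(train_t, config.window)
    result = adasyn_balance(tw.flat, tw.y, config.adasyn)
    t_balanced = np.concatenate(
        [tw.t_end, np.array([tw.t_end[p] for p, _, _ in result.provenance], dtype=int)]
    )
    return SplitResult(
        train_panel=train_panel,
        test_panel=test_panel,
        params=params,
        train_windows=tw,
        X_balanced=result.X_balanced,
        y_balanced=result.y_balanced,
        t_balanced=t_balanced,
        adasyn=result,
        test_hash=test_hash,
    )


def summarize_cv(results: list[FitResult]) -> dict:
    acc = np.array([r.report.metrics["accuracy"] for r in results])
    return {
        "fold_accuracy": acc.tolist(),
        "mean_accuracy": float(acc.mean()),
        "sd_accuracy": float(acc.std(ddof=1)) if len(acc) > 1 else 0.0,
    }
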