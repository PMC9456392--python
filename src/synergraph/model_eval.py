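"""Gradient-boosted classification and cross-validated evaluation.

The classifier is XGBoost's ``gbtree`` booster with the settings the pipeline
defaults to (depth 7, learning rate 0.1, 90% row/column subsampling, gamma
0.1, min_child_weight 1), trained single-threaded so runs are reproducible
from a seed.

Evaluation reports six metrics — accuracy, recall, precision, F1, AUC-ROC and
AUC-PR (average precision) — under repeated stratified k-fold
cross-validation.  Splits are made at the level of synergy *records*;
symmetrized drug orderings are created only inside each training fold, and
held-out predictions average the two orderings of each test record, so a
record never straddles a split and predictions are order-invariant.

Out-of-fold scores are retained per record and per repeat, which is what the
per-cell-line / per-tissue stratified AUC summaries pool over.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import GroupKFold, StratifiedKFold
from xgboost import XGBClassifier

from .featurize import FeatureTable

logger = logging.getLogger(__name__)

METRICS = ("acc", "recall", "precision", "f1", "auc_roc", "auc_pr")


@dataclass(frozen=True)
class BoostConfig:
    """XGBoost settings; defaults are the pipeline's tuned values."""

    booster: str = "gbtree"
    max_depth: int = 7
    min_child_weight: float = 1
    gamma: float = 0.1
    subsample: float = 0.9
    colsample_bytree: float = 0.9
    learning_rate: float = 0.1
    n_rounds: int = 100
    seed: int = 0

    def xgb_params(self) -> dict:
        return dict(
            booster=self.booster,
            max_depth=self.max_depth,
            min_child_weight=self.min_child_weight,
            gamma=self.gamma,
            subsample=self.subsample,
            colsample_bytree=self.colsample_bytree,
            learning_rate=self.learning_rate,
            n_estimators=self.n_rounds,
            random_state=self.seed,
            n_jobs=1,
            eval_metric="logloss",
        )


def train_classifier(
    X: np.ndarray | FeatureTable,
    y: np.ndarray | None = None,
    cfg: BoostConfig | None = None,
) -> XGBClassifier:
    """Fit the boosted-tree classifier on feature rows.

    Accepts either a :class:`FeatureTable` or an explicit ``(X, y)`` pair.
    Both classes must be present.
    """
    if isinstance(X, FeatureTable):
        X, y = X.X, X.y
    if y is None:
        raise ValueError("labels are required")
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data contains a single class")
    if min(np.sum(y == c) for c in classes) < 2:
        raise ValueError("need at least 2 rows of each class")
    cfg = cfg or BoostConfig()
    model = XGBClassifier(**cfg.xgb_params())
    model.fit(np.asarray(X, dtype=float), y)
    return model


def evaluate(y_true, y_score, threshold: float = 0.5) -> dict[str, float]:
    """The six-metric bundle for one set of scores.

    Thresholded metrics use ``score >= threshold``; AUC-ROC is the trapezoidal
    area under the ROC curve and AUC-PR is average precision.  Both classes
    must appear in ``y_true`` (the AUCs are undefined otherwise).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_score = np.asarray(y_score, dtype=float)
    if y_true.shape != y_score.shape:
        raise ValueError("y_true and y_score must have equal length")
    if np.unique(y_true).size < 2:
        raise ValueError("both classes required: AUCs undefined for one class")
    y_pred = (y_score >= threshold).astype(int)
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    acc = (tp + tn) / y_true.size
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return {
        "acc": acc,
        "recall": recall,
        "precision": precision,
        "f1": f1,
        "auc_roc": float(roc_auc_score(y_true, y_score)),
        "auc_pr": float(average_precision_score(y_true, y_score)),
    }


@dataclass
class CVResult:
    """Everything a repeated stratified cross-validation run produced."""

    fold_metrics: pd.DataFrame           # repeat, fold + the six metrics
    y: np.ndarray                        # record labels
    meta: pd.DataFrame                   # record metadata (drug_a, drug_b, cell, tissue)
    oof_scores: np.ndarray               # (repeats, n) out-of-fold scores
    fold_of: np.ndarray                  # (repeats, n) test-fold index per record
    roc_curves: dict = field(default_factory=dict)  # (repeat, fold) -> (fpr, tpr)

    @property
    def summary(self) -> pd.DataFrame:
        """Mean ± sd of each metric over all repeat × fold cells."""
        stats = self.fold_metrics[list(METRICS)].agg(["mean", "std"])
        return stats.T.rename(columns={"std": "sd"})

    def mean(self, metric: str) -> float:
        return float(self.fold_metrics[metric].mean())

    def save(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.fold_metrics.to_csv(outdir / "fold_metrics.csv", index=False)
        summary = {
            m: {"mean": float(self.fold_metrics[m].mean()),
                "sd": float(self.fold_metrics[m].std())}
            for m in METRICS
        }
        (outdir / "cv_metrics.json").write_text(json.dumps(summary, indent=2))
        points = [
            {"repeat": r, "fold": f, "fpr": fpr.tolist(), "tpr": tpr.tolist()}
            for (r, f), (fpr, tpr) in self.roc_curves.items()
        ]
        rows = [
            (p["repeat"], p["fold"], x, y)
            for p in points
            for x, y in zip(p["fpr"], p["tpr"])
        ]
        pd.DataFrame(rows, columns=["repeat", "fold", "fpr", "tpr"]).to_csv(
            outdir / "roc_points.csv", index=False
        )


def _symmetrized_training_rows(table: FeatureTable, idx: np.ndarray):
    X = np.concatenate([table.X[idx], table.swapped()[idx]], axis=0)
    y = np.concatenate([table.y[idx], table.y[idx]])
    return X, y


def cross_validate(
    table: FeatureTable,
    folds: int = 5,
    repeats: int = 5,
    cfg: BoostConfig | None = None,
    symmetrize: bool = True,
    split_by: str = "record",
) -> CVResult:
    """Repeated stratified k-fold cross-validation over synergy records.

    Each repeat draws fresh stratified splits from a seed derived from
    ``cfg.seed``.  Training folds are symmetrized (both drug orderings);
    test predictions average the model's scores for the two orderings.

    ``split_by="cell"`` switches to leave-cell-lines-out splitting (grouped,
    not stratified): every record of a held-out cell line lands in the same
    test fold.  This is a stricter generalisation probe than the standard
    record-level protocol and is not part of it.
    """
    cfg = cfg or BoostConfig()
    if split_by not in ("record", "cell"):
        raise ValueError(f"split_by must be 'record' or 'cell', got {split_by!r}")
    n = len(table)
    swapped = table.swapped()
    oof = np.full((repeats, n), np.nan)
    fold_of = np.full((repeats, n), -1, dtype=int)
    rows = []
    curves: dict = {}
    for rep in range(repeats):
        if split_by == "cell":
            splitter = GroupKFold(
                n_splits=folds, shuffle=True, random_state=cfg.seed + 1000 * rep
            )
            split = splitter.split(table.X, table.y, groups=table.meta["cell"])
        else:
            splitter = StratifiedKFold(
                n_splits=folds, shuffle=True, random_state=cfg.seed + 1000 * rep
            )
            split = splitter.split(table.X, table.y)
        for fold, (tr, te) in enumerate(split):
            if symmetrize:
                X_tr, y_tr = _symmetrized_training_rows(table, tr)
            else:
                X_tr, y_tr = table.X[tr], table.y[tr]
            model = train_classifier(
                X_tr, y_tr, replace(cfg, seed=cfg.seed + 1000 * rep + fold)
            )
            score = 0.5 * (
                model.predict_proba(table.X[te])[:, 1]
                + model.predict_proba(swapped[te])[:, 1]
            )
            oof[rep, te] = score
            fold_of[rep, te] = fold
            metrics = evaluate(table.y[te], score)
            rows.append({"repeat": rep, "fold": fold, **metrics})
            fpr, tpr, _ = roc_curve(table.y[te], score)
            curves[(rep, fold)] = (fpr, tpr)
    result = CVResult(
        fold_metrics=pd.DataFrame(rows),
        y=table.y.copy(),
        meta=table.meta.reset_index(drop=True),
        oof_scores=oof,
        fold_of=fold_of,
        roc_curves=curves,
    )
    logger.info(
        "cross_validate: %d folds x %d repeats, mean AUC-ROC %.3f",
        folds, repeats, result.mean("auc_roc"),
    )
    return result


def stratified_performance(
    cvres: CVResult,
    metadata: pd.DataFrame | None = None,
    by: str = "cell",
) -> pd.DataFrame:
    """Per-cell-line or per-tissue AUC-ROC over pooled out-of-fold scores.

    Scores from every repeat are pooled per group.  Groups whose records are
    all one class get ``NaN`` (undefined), never silently dropped.
    """
    if by not in ("cell", "tissue"):
        raise ValueError(f"grouping key must be 'cell' or 'tissue', got {by!r}")
    meta = metadata if metadata is not None else cvres.meta
    groups = meta[by].to_numpy()
    out = []
    for group in sorted(pd.unique(groups)):
        mask = groups == group
        y = np.tile(cvres.y[mask], cvres.oof_scores.shape[0])
        s = cvres.oof_scores[:, mask].ravel()
        n_pos = int(cvres.y[mask].sum())
        n_neg = int(mask.sum() - n_pos)
        auc = roc_auc_score(y, s) if n_pos and n_neg else np.nan
        out.append(
            {by: group, "n_records": int(mask.sum()), "n_pos": n_pos,
             "n_neg": n_neg, "auc_roc": auc}
        )
    return pd.DataFrame(out)


def grid_search(
    table: FeatureTable,
    param_grid: dict[str, list],
    folds: int = 5,
    base_cfg: BoostConfig | None = None,
) -> tuple[BoostConfig, pd.DataFrame]:
    """Exhaustive grid search scored by mean cross-validated AUC-ROC.

    Ties are broken toward the smaller ``max_depth``, then the lower
    ``learning_rate``.  Returns the winning config and the full score table.
    """
    if not param_grid or any(len(v) == 0 for v in param_grid.values()):
        raise ValueError("parameter grid is empty")
    base_cfg = base_cfg or BoostConfig()
    unknown = set(param_grid) - set(asdict(base_cfg))
    if unknown:
        raise ValueError(f"unknown grid parameters: {sorted(unknown)}")
    keys = sorted(param_grid)
    rows = []
    candidates: list[tuple[float, BoostConfig]] = []
    for values in itertools.product(*(param_grid[k] for k in keys)):
        cfg = replace(base_cfg, **dict(zip(keys, values)))
        score = cross_validate(table, folds=folds, repeats=1, cfg=cfg).mean("auc_roc")
        rows.append({**dict(zip(keys, values)), "mean_auc_roc": score})
        candidates.append((score, cfg))
    best = max(
        candidates,
        key=lambda sc: (sc[0], -sc[1].max_depth, -sc[1].learning_rate),
    )[1]
    return best, pd.DataFrame(rows)
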