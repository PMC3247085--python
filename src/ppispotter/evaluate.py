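"""Evaluation: positive-class precision/recall/F1, rank-based AUC,
stratified 10-fold cross-validation and learning curves over labeled-set
sizes.

Cross-validation mirrors the intended deployment: within each fold the
training portion is split into a small labeled subset and a large
unlabeled pool (whose gold labels drive the simulated expert oracle), the
chosen method is trained, and metrics are computed on the held-out fold.
Learning curves are transductive: for each labeled-set size the labeled
sentences are sampled at random and the remainder serves as the unlabeled
test set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .active import GoldLabelOracle
from .driver import RunConfig, run_method
from .features import EncodingSpec, FeatureRecord
from .svm import decision_value

logger = logging.getLogger(__name__)


@dataclass
class EvalReport:
    """Aggregate positive-class metrics with per-fold detail."""

    precision: float
    recall: float
    f1: float
    auc: float
    per_fold: list[dict] = field(default_factory=list)
    n_folds: int = 0
    seed: int = 0
    config: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "auc": self.auc, "per_fold": self.per_fold, "n_folds": self.n_folds,
            "seed": self.seed, "config": self.config,
        }


def prf(y_true, y_pred) -> tuple[float, float, float]:
    """Positive-class precision, recall and F1; zero denominators yield 0
    with a logged warning."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    tp = int(((y_true > 0) & (y_pred > 0)).sum())
    fp = int(((y_true < 0) & (y_pred > 0)).sum())
    fn = int(((y_true > 0) & (y_pred < 0)).sum())
    if tp + fp == 0 or tp + fn == 0:
        logger.warning("degenerate contingency table (tp=%d fp=%d fn=%d)", tp, fp, fn)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def auc(y_true, scores) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve, ties counted
    one half."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC requires both classes")
    return float(roc_auc_score((y_true > 0).astype(int), np.asarray(scores, dtype=float)))


def _encode_fold(features, train_rows, eval_rows):
    """Numeric matrices for one fold; encoding statistics come from the
    training rows only (no leakage)."""
    if isinstance(features, np.ndarray):
        return features[train_rows], features[eval_rows]
    records = list(features)
    spec = EncodingSpec().fit([records[i] for i in train_rows])
    X_tr, _ = spec.transform([records[i] for i in train_rows])
    X_ev, _ = spec.transform([records[i] for i in eval_rows])
    return X_tr, X_ev


def _split_labeled(y_train, n_labeled, rng) -> np.ndarray:
    """Stratified labeled subset of the training rows."""
    idx_pos = np.flatnonzero(y_train > 0)
    idx_neg = np.flatnonzero(y_train < 0)
    n_pos = max(1, round(n_labeled * len(idx_pos) / len(y_train)))
    n_pos = min(n_pos, n_labeled - 1, len(idx_pos))
    n_neg = min(n_labeled - n_pos, len(idx_neg))
    chosen = np.concatenate([
        rng.choice(idx_pos, size=n_pos, replace=False),
        rng.choice(idx_neg, size=n_neg, replace=False),
    ])
    return np.sort(chosen)


def kfold_cv(
    features,
    y,
    method: str,
    config: RunConfig | None = None,
    n_folds: int = 10,
    n_labeled: int = 50,
    seed: int = 0,
) -> EvalReport:
    """Stratified, seeded k-fold cross-validation of one method.

    ``features`` is either a numeric matrix or a list of feature records
    (encoded per fold on training rows only).  Within each fold,
    ``n_labeled`` training rows form the labeled set and the remaining
    training rows the unlabeled pool; gold labels of the pool feed the
    simulated oracle.  The aggregate is the unweighted mean over folds.
    """
    y = np.asarray(y)
    if config is None:
        config = RunConfig(method=method, seed=seed)
    counts = [int((y > 0).sum()), int((y < 0).sum())]
    if min(counts) < n_folds:
        raise ValueError(f"need >= {n_folds} examples per class, have {counts}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)
    per_fold = []
    for fold, (train_rows, eval_rows) in enumerate(skf.split(np.zeros(len(y)), y)):
        X_tr, X_ev = _encode_fold(features, train_rows, eval_rows)
        y_tr, y_ev = y[train_rows], y[eval_rows]
        lab_loc = _split_labeled(y_tr, min(n_labeled, len(y_tr) - 1), rng)
        oracle = GoldLabelOracle(y_tr)
        fit = run_method(method, X_tr, lab_loc, y_tr[lab_loc], oracle=oracle, config=config)
        scores = decision_value(fit.model, X_ev)
        y_hat = np.where(scores >= 0, 1, -1)
        p, r, f = prf(y_ev, y_hat)
        fold_auc = auc(y_ev, scores) if len(np.unique(y_ev)) > 1 else np.nan
        per_fold.append({"fold": fold, "precision": p, "recall": r, "f1": f,
                         "auc": fold_auc,
                         "oracle_calls": fit.report.get("oracle_calls", 0)})
    agg = {k: float(np.nanmean([pf[k] for pf in per_fold]))
           for k in ("precision", "recall", "f1", "auc")}
    return EvalReport(precision=agg["precision"], recall=agg["recall"], f1=agg["f1"],
                      auc=agg["auc"], per_fold=per_fold, n_folds=n_folds, seed=seed,
                      config=config.echo())


def learning_curve(
    features,
    y,
    methods: list[str],
    sizes: list[int],
    n_runs: int = 10,
    seed: int = 0,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Transductive learning curve: mean (+/- sd) F1 per labeled-set size
    and method, averaged over ``n_runs`` random labeled samples; the
    unlabeled remainder is the test set.  Sizes that leave no remainder
    are skipped with a warning.
    """
    y = np.asarray(y)
    n = len(y)
    rows = []
    for size in sizes:
        if size >= n:
            logger.warning("labeled size %d >= corpus size %d; row skipped", size, n)
            continue
        for method in methods:
            f1s = []
            for run in range(n_runs):
                rng = np.random.default_rng((seed * 100003 + size * 131 + run) % (2**31))
                lab = rng.choice(n, size=size, replace=False)
                if len(np.unique(y[lab])) < 2:  # resample until both classes present
                    tries = 0
                    while len(np.unique(y[lab])) < 2 and tries < 50:
                        lab = rng.choice(n, size=size, replace=False)
                        tries += 1
                    if len(np.unique(y[lab])) < 2:
                        continue
                rest = np.array(sorted(set(range(n)) - set(lab.tolist())))
                run_cfg = config if config is not None else RunConfig(method=method, seed=seed + run)
                if isinstance(features, np.ndarray):
                    X = features
                else:
                    spec = EncodingSpec().fit([features[i] for i in lab])
                    X, _ = spec.transform(list(features))
                oracle = GoldLabelOracle(y)
                fit = run_method(method, X, lab, y[lab], oracle=oracle, config=run_cfg)
                scores = decision_value(fit.model, X[rest])
                _, _, f1 = prf(y[rest], np.where(scores >= 0, 1, -1))
                f1s.append(f1)
            if f1s:
                rows.append({"size": size, "method": method,
                             "mean_f1": float(np.mean(f1s)),
                             "sd_f1": float(np.std(f1s, ddof=1)) if len(f1s) > 1 else 0.0,
                             "n_runs": len(f1s)})
    return pd.DataFrame(rows, columns=["size", "method", "mean_f1", "sd_f1", "n_runs"])
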