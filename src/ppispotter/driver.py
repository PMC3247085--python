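"""The combined break-tie + deterministic-annealing classifier (BTDA-SVM)
and its comparison methods.

Data are partitioned into four disjoint index sets over one feature
matrix: S_t (initially labeled), S_k (labeled by the oracle during active
learning), S_u (still unlabeled) and S_h (machine-labeled with high
confidence).  Each active-learning round trains a supervised SVM with
calibrated probabilities on the current labeled set, splits the pool by
confidence, and sends the most tied fuzzy instances to the oracle.  The
final annealing stage does not discard the high-confidence machine labels:
it warm-starts the soft labels of S_h at the calibrated machine
probabilities (0.5 elsewhere), which is what distinguishes the combined
method from running the semi-supervised stage cold.

Baselines: plain supervised SVM on S_t; random sampling of oracle queries
(RS); k-means cluster-then-label (C-SVM); break-tie active learning
without the annealing stage (BT).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
from sklearn.cluster import KMeans

from .active import GoldLabelOracle, select_queries, split_by_confidence
from .annealing import AnnealingSchedule, DAState, anneal
from .svm import Calibration, LinearModel, class_probability, fit_calibration, train_linear_svm

METHODS = ("svm", "rs", "cluster", "bt", "btda")


@dataclass
class RunConfig:
    """Configuration for one training run; serialized verbatim into every
    report for reproducibility."""

    method: str = "btda"
    C: float = 1.0
    C_star: float = 1.0
    rounds: int = 1
    budget: int = 20
    theta: float = 0.9
    schedule: AnnealingSchedule = field(default_factory=AnnealingSchedule)
    seed: int = 0
    balance: bool = False
    post_da: bool = False
    k_clusters: int = 2

    def echo(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class PartitionedData:
    """Disjoint index sets over the pooled feature matrix."""

    S_t: np.ndarray
    S_k: np.ndarray
    S_u: np.ndarray
    S_h: np.ndarray
    soft_labels: dict[int, float] = field(default_factory=dict)

    def check(self, n_total: int) -> None:
        parts = [self.S_t, self.S_k, self.S_u, self.S_h]
        allidx = np.concatenate([np.asarray(p, dtype=int) for p in parts])
        if len(set(allidx.tolist())) != len(allidx) or len(allidx) != n_total:
            raise AssertionError("partition must be disjoint and exhaustive")


@dataclass
class FitResult:
    model: LinearModel
    calibration: Calibration | None
    partition: PartitionedData | None
    da_state: DAState | None
    report: dict


def _supervised(X, y, C):
    model = train_linear_svm(X, y, C=C)
    calib = fit_calibration(model, X, y)
    return model, calib


def _balance_target(y_l) -> float:
    return float((np.asarray(y_l) > 0).mean())


def _al_rounds(X, labeled_idx, y_labeled, oracle, config):
    """Shared steps 1-3 of the combined algorithm: per round, train and
    calibrate on the current labeled set, split the pool by confidence,
    and query the oracle on the most tied fuzzy instances."""
    n = len(X)
    S_t = np.asarray(labeled_idx, dtype=int)
    y_map = {int(i): int(lab) for i, lab in zip(S_t, y_labeled)}
    S_k: list[int] = []
    pool = np.array(sorted(set(range(n)) - set(S_t.tolist())), dtype=int)
    model = calib = None
    S_h = np.empty(0, dtype=int)
    soft: dict[int, float] = {}

    for _ in range(max(config.rounds, 1)):
        lab_idx = np.concatenate([S_t, np.asarray(S_k, dtype=int)])
        y_lab = np.array([y_map[int(i)] for i in lab_idx])
        model, calib = _supervised(X[lab_idx], y_lab, config.C)
        if len(pool) == 0:
            S_h = np.empty(0, dtype=int)
            soft = {}
            break
        p_pos, _ = class_probability(model, calib, X[pool])
        fuzzy_loc, conf_loc, _ = split_by_confidence(p_pos, config.theta)
        S_h = pool[conf_loc]
        soft = {int(i): float(p) for i, p in zip(pool[conf_loc], p_pos[conf_loc])}
        if config.budget > 0 and len(fuzzy_loc) > 0:
            batch = select_queries(p_pos[fuzzy_loc], config.budget)
            queried = pool[fuzzy_loc[batch.indices]]
            for i in queried:
                y_map[int(i)] = oracle.query(int(i))
                S_k.append(int(i))
            pool = np.array(sorted(set(pool.tolist()) - set(queried.tolist())), dtype=int)
            # refresh confidence sets against the remaining pool
            S_h = np.array(sorted(set(S_h.tolist()) - set(queried.tolist())), dtype=int)
            soft = {i: p for i, p in soft.items() if i in set(S_h.tolist())}

    S_k = np.asarray(sorted(S_k), dtype=int)
    S_u = np.array(sorted(set(pool.tolist()) - set(S_h.tolist())), dtype=int)
    part = PartitionedData(S_t=S_t, S_k=S_k, S_u=S_u, S_h=S_h, soft_labels=soft)
    part.check(n)
    return model, calib, part, y_map


def run_supervised(X, labeled_idx, y_labeled, config: RunConfig) -> FitResult:
    """Baseline: linear SVM on the initially labeled set only."""
    model, calib = _supervised(X[np.asarray(labeled_idx, dtype=int)],
                               np.asarray(y_labeled), config.C)
    report = {"method": "svm", "config": config.echo(), "oracle_calls": 0,
              "n_labeled_final": len(labeled_idx)}
    return FitResult(model, calib, None, None, report)


def run_bt(X, labeled_idx, y_labeled, oracle, config: RunConfig) -> FitResult:
    """Break-tie active learning: AL rounds, then a supervised SVM on the
    enlarged labeled set (no annealing stage)."""
    model, calib, part, y_map = _al_rounds(X, labeled_idx, y_labeled, oracle, config)
    lab_idx = np.concatenate([part.S_t, part.S_k])
    y_lab = np.array([y_map[int(i)] for i in lab_idx])
    model, calib = _supervised(X[lab_idx], y_lab, config.C)
    report = {"method": "bt", "config": config.echo(),
              "oracle_calls": getattr(oracle, "n_calls", None),
              "n_labeled_final": len(lab_idx)}
    return FitResult(model, calib, part, None, report)


def run_btda(X, labeled_idx, y_labeled, oracle, config: RunConfig) -> FitResult:
    """The combined algorithm: break-tie AL rounds followed by the
    annealing stage warm-started from the machine probabilities of the
    high-confidence set.

    In the annealing stage the per-point unlabeled penalty is
    ``C* . C . |L| / |U|`` (equal-mass convention: the total influence of
    the unlabeled pool matches ``C*`` times that of the labeled set), so
    the labeled anchors are not drowned out by a large pool.  When the
    balance constraint is on, its target ratio comes from the initially
    labeled set only: the actively queried labels concentrate near the
    decision boundary and are not a representative class sample.
    """
    _, _, part, y_map = _al_rounds(X, labeled_idx, y_labeled, oracle, config)
    lab_idx = np.concatenate([part.S_t, part.S_k])
    y_lab = np.array([y_map[int(i)] for i in lab_idx])
    unl_idx = np.concatenate([part.S_h, part.S_u])
    p_init = np.concatenate([
        np.array([part.soft_labels[int(i)] for i in part.S_h], dtype=float),
        np.full(len(part.S_u), 0.5),
    ])
    balance = _balance_target(np.asarray(y_labeled)) if config.balance else None
    if len(unl_idx):
        c_star_pt = config.C_star * config.C * len(lab_idx) / len(unl_idx)
        state = anneal(X[lab_idx], y_lab, X[unl_idx], schedule=config.schedule,
                       C=config.C, C_star=c_star_pt, p_init=p_init, balance=balance)
    else:
        state = anneal(X[lab_idx], y_lab, np.empty((0, X.shape[1])),
                       schedule=config.schedule, C=config.C, C_star=config.C_star)
    calib = fit_calibration(state.model, X[lab_idx], y_lab)
    report = {"method": "btda", "config": config.echo(),
              "oracle_calls": getattr(oracle, "n_calls", None),
              "n_labeled_final": len(lab_idx),
              "da_free_energy": state.free_energy, "da_entropy": state.entropy}
    return FitResult(state.model, calib, part, state, report)


def run_rs(X, labeled_idx, y_labeled, oracle, config: RunConfig) -> FitResult:
    """Random-sampling baseline: a seeded uniform sample of pool instances
    is oracle-labeled and a supervised SVM is trained on the union.  With
    ``post_da`` the annealing stage runs afterwards on the remainder."""
    rng = np.random.default_rng(config.seed)
    S_t = np.asarray(labeled_idx, dtype=int)
    pool = np.array(sorted(set(range(len(X))) - set(S_t.tolist())), dtype=int)
    k = min(config.budget, len(pool))
    chosen = np.sort(rng.choice(pool, size=k, replace=False)) if k else np.empty(0, dtype=int)
    y_map = {int(i): int(lab) for i, lab in zip(S_t, y_labeled)}
    for i in chosen:
        y_map[int(i)] = oracle.query(int(i))
    lab_idx = np.concatenate([S_t, chosen])
    y_lab = np.array([y_map[int(i)] for i in lab_idx])
    rest = np.array(sorted(set(pool.tolist()) - set(chosen.tolist())), dtype=int)
    if config.post_da and len(rest):
        state = anneal(X[lab_idx], y_lab, X[rest], schedule=config.schedule,
                       C=config.C,
                       C_star=config.C_star * config.C * len(lab_idx) / len(rest))
        model = state.model
    else:
        state = None
        model, _ = _supervised(X[lab_idx], y_lab, config.C)
    calib = fit_calibration(model, X[lab_idx], y_lab)
    part = PartitionedData(S_t=S_t, S_k=chosen, S_u=rest, S_h=np.empty(0, dtype=int))
    report = {"method": "rs", "config": config.echo(),
              "oracle_calls": getattr(oracle, "n_calls", None),
              "n_labeled_final": len(lab_idx)}
    return FitResult(model, calib, part, state, report)


def run_cluster(X, labeled_idx, y_labeled, config: RunConfig) -> FitResult:
    """Cluster-then-label baseline: seeded k-means over all points; every
    cluster takes the majority label of its labeled members (clusters with
    none take the label of the nearest labeled point by centroid
    distance); a supervised SVM is trained on all pseudo-labeled data."""
    S_t = np.asarray(labeled_idx, dtype=int)
    y_l = np.asarray(y_labeled)
    k = max(config.k_clusters, 1)
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=config.seed)
    assign = km.fit_predict(X)
    cluster_label = {}
    for c in range(k):
        members = [i for i, lab_i in zip(S_t, y_l) if assign[i] == c]
        if members:
            labs = np.array([y_l[list(S_t).index(i)] for i in members])
            maj = 1 if (labs > 0).sum() * 2 >= len(labs) else -1
            cluster_label[c] = maj
        else:
            d = np.linalg.norm(X[S_t] - km.cluster_centers_[c], axis=1)
            cluster_label[c] = int(y_l[int(np.argmin(d))])
    y_pseudo = np.array([cluster_label[c] for c in assign])
    y_pseudo[S_t] = y_l  # gold labels take precedence
    if len(np.unique(y_pseudo)) < 2:
        # degenerate propagation: fall back to nearest-labeled-point labels
        from scipy.spatial.distance import cdist

        nearest = np.argmin(cdist(X, X[S_t]), axis=1)
        y_pseudo = y_l[nearest]
        y_pseudo[S_t] = y_l
    model, calib = _supervised(X, y_pseudo, config.C)
    part = PartitionedData(
        S_t=S_t,
        S_k=np.empty(0, dtype=int),
        S_u=np.array(sorted(set(range(len(X))) - set(S_t.tolist())), dtype=int),
        S_h=np.empty(0, dtype=int),
    )
    report = {"method": "cluster", "config": config.echo(), "oracle_calls": 0,
              "n_labeled_final": len(S_t)}
    return FitResult(model, calib, part, None, report)


def run_method(
    method: str,
    X: np.ndarray,
    labeled_idx,
    y_labeled,
    oracle=None,
    config: RunConfig | None = None,
) -> FitResult:
    """Dispatch one of the five methods; stochastic ones require a seeded
    config and an oracle where applicable."""
    if config is None:
        config = RunConfig(method=method)
    if method == "svm":
        return run_supervised(X, labeled_idx, y_labeled, config)
    if method == "cluster":
        return run_cluster(X, labeled_idx, y_labeled, config)
    if oracle is None:
        oracle = GoldLabelOracle({})
    if method == "rs":
        return run_rs(X, labeled_idx, y_labeled, oracle, config)
    if method == "bt":
        return run_bt(X, labeled_idx, y_labeled, oracle, config)
    if method == "btda":
        return run_btda(X, labeled_idx, y_labeled, oracle, config)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
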