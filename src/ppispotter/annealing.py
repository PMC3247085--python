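"""Deterministic-annealing semi-supervised SVM.

The transductive SVM objective assigns hard labels to unlabeled points;
deterministic annealing relaxes those discrete labels to Bernoulli
probabilities p_j = P(y'_j = +1) and minimizes the free energy

    F(w, b, p; T) = 1/2 ||w||^2
                  + C  * sum_{i in L} H1(y_i f(x_i))
                  + C* * sum_{j in U} [ p_j H1(f(x_j)) + (1-p_j) H1(-f(x_j)) ]
                  - T  * sum_{j in U} S(p_j)

with H1(t) = max(0, 1-t) the hinge loss and S the Shannon entropy of a
Bernoulli variable.  At high temperature T the entropy term dominates and
the soft labels sit near 0.5; as T is lowered along the annealing
schedule, each problem warm-starts from the previous solution and the
labels harden toward {0, 1}.

Both block updates are exact: the (w, b) step is a weighted SVM fit with
each unlabeled point duplicated under both labels, and the p step has the
closed form p_j = 1 / (1 + exp(g_j / T)) with
g_j = C* (H1(f_j) - H1(-f_j)), optionally shifted by a multiplier to hit
a target class balance.  Block coordinate descent therefore never
increases the free energy at fixed T.  No global optimality is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .svm import LinearModel, decision_value, train_linear_svm


def _hinge(t: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, 1.0 - t)


def bernoulli_entropy(p: np.ndarray) -> np.ndarray:
    """-p ln p - (1-p) ln(1-p), with 0 ln 0 = 0."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = -np.where(p > 0, p * np.log(p), 0.0) - np.where(
            p < 1, (1 - p) * np.log(1 - p), 0.0
        )
    return out


@dataclass
class AnnealingSchedule:
    """Temperature sequence T0, T0/R, T0/R^2, ... with stopping thresholds.

    ``inner_tol`` bounds the symmetrized KL divergence between consecutive
    soft-label vectors inside a fixed-T loop; the outer loop stops when the
    total soft-label entropy drops below ``entropy_tol`` (by default
    1e-6 per unlabeled point) or the temperature passes ``T_min``.
    """

    T0: float = 10.0
    R: float = 1.5
    T_min: float = 1e-4
    inner_tol: float = 1e-6
    inner_max: int = 50
    entropy_tol: float | None = None  # None -> 1e-6 * |U|

    def __post_init__(self):
        if not (self.T0 > 0 and self.R > 1 and self.T_min > 0):
            raise ValueError("require T0 > 0, R > 1, T_min > 0")
        if self.inner_tol <= 0 or self.inner_max < 1:
            raise ValueError("inner thresholds must be positive")

    def temperatures(self):
        T = self.T0
        while T >= self.T_min:
            yield T
            T /= self.R


@dataclass
class DAState:
    """Solution state: model, soft labels, temperature, free energy and the
    full per-iteration trace.

    ``objective`` is the temperature-free part of the free energy (the
    expected transductive SVM objective E_p[F]); it is the quantity states
    from different temperatures are compared on, since the -T*S homotopy
    term is not commensurable across temperatures.
    """

    model: LinearModel
    p: np.ndarray
    T: float
    free_energy: float
    entropy: float
    objective: float = 0.0
    trace: list[dict] = field(default_factory=list)


def free_energy(
    model: LinearModel,
    p: np.ndarray,
    T: float,
    X_l: np.ndarray,
    y_l: np.ndarray,
    X_u: np.ndarray,
    C: float = 1.0,
    C_star: float = 1.0,
) -> float:
    """The annealed objective at (w, b, p, T); with no unlabeled points it
    reduces exactly to the supervised SVM objective."""
    if T < 0:
        raise ValueError("temperature must be non-negative")
    val = 0.5 * float(model.w @ model.w)
    if len(X_l):
        val += C * float(np.sum(_hinge(np.asarray(y_l, dtype=float) * decision_value(model, X_l))))
    if len(X_u):
        f = decision_value(model, X_u)
        p = np.asarray(p, dtype=float)
        val += C_star * float(np.sum(p * _hinge(f) + (1 - p) * _hinge(-f)))
        val -= T * float(np.sum(bernoulli_entropy(p)))
    return val


def update_soft_labels(
    model: LinearModel,
    X_u: np.ndarray,
    T: float,
    C_star: float = 1.0,
    balance: float | None = None,
) -> np.ndarray:
    """Exact minimizer of the free energy in p at fixed (w, b).

    Without a balance target: p_j = 1/(1 + exp(g_j / T)).  With a target
    ratio r, a multiplier nu shifts every g_j so that mean(p) = r
    (bisection to 1e-8).
    """
    if T <= 0:
        raise ValueError("T must be positive; use round_labels at T=0")
    f = np.asarray(decision_value(model, X_u), dtype=float)
    g = C_star * (_hinge(f) - _hinge(-f))

    def p_of(nu: float) -> np.ndarray:
        z = np.clip((g - nu) / T, -700, 700)
        return 1.0 / (1.0 + np.exp(z))

    if balance is None:
        return p_of(0.0)
    lo = float(g.min()) - 40.0 * T
    hi = float(g.max()) + 40.0 * T
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        m = float(p_of(mid).mean())
        if abs(m - balance) <= 1e-8:
            break
        if m < balance:
            lo = mid  # larger nu -> larger p
        else:
            hi = mid
    return p_of(mid)


def weighted_train(
    X_l: np.ndarray,
    y_l: np.ndarray,
    X_u: np.ndarray,
    p: np.ndarray,
    C: float = 1.0,
    C_star: float = 1.0,
) -> LinearModel:
    """Exact minimizer of the free energy in (w, b) at fixed p.

    Each unlabeled point appears twice: once with label +1 and weight
    C* p_j, once with label -1 and weight C* (1-p_j); labeled points carry
    weight C.  A single weighted SVM fit then solves the block problem.
    The duplicated dual is degenerate, so the solve runs at a moderate
    tolerance; the annealing loop's monotone safeguard absorbs the
    residual inexactness.
    """
    if len(X_u) == 0:
        return train_linear_svm(X_l, y_l, C=1.0, sample_weights=np.full(len(y_l), C))
    p = np.asarray(p, dtype=float)
    X = np.vstack([X_l, X_u, X_u])
    y = np.concatenate([y_l, np.ones(len(X_u)), -np.ones(len(X_u))])
    s = np.concatenate([np.full(len(y_l), C), C_star * p, C_star * (1.0 - p)])
    return train_linear_svm(X, y, C=1.0, sample_weights=s, tol=1e-6, max_iter=50_000)


def round_labels(p: np.ndarray) -> np.ndarray:
    """Harden soft labels: sign(2p - 1), with exact ties (p = 0.5) -> +1."""
    p = np.asarray(p, dtype=float)
    return np.where(p >= 0.5, 1, -1)


def _sym_kl(p: np.ndarray, q: np.ndarray) -> float:
    """Symmetrized Bernoulli KL divergence between consecutive soft-label
    vectors (the inner-loop convergence statistic)."""
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    q = np.clip(q, eps, 1 - eps)
    kl_pq = p * np.log(p / q) + (1 - p) * np.log((1 - p) / (1 - q))
    kl_qp = q * np.log(q / p) + (1 - q) * np.log((1 - q) / (1 - p))
    return float(np.sum(kl_pq + kl_qp))


def anneal(
    X_l: np.ndarray,
    y_l: np.ndarray,
    X_u: np.ndarray,
    schedule: AnnealingSchedule | None = None,
    C: float = 1.0,
    C_star: float = 1.0,
    p_init: np.ndarray | None = None,
    balance: float | None = None,
) -> DAState:
    """Run the full annealing loop.

    The outer loop walks the temperature schedule; at each T an inner
    block-coordinate loop alternates the weighted SVM fit and the
    closed-form soft-label update until the symmetrized KL between
    consecutive p vectors falls below ``inner_tol`` (or ``inner_max``
    iterations).  The outer loop stops once the total entropy of p falls
    below ``entropy_tol`` or T reaches ``T_min``.  The returned state is
    the recorded one minimizing the temperature-free objective E_p[F]
    (free energies at different temperatures are not comparable because
    of the -T*S term; on ties the later, colder state wins).  The full
    trace is kept.
    """
    if schedule is None:
        schedule = AnnealingSchedule()
    X_l = np.atleast_2d(np.asarray(X_l, dtype=float))
    y_l = np.asarray(y_l, dtype=float)
    X_u = np.asarray(X_u, dtype=float)
    if X_u.size == 0:
        X_u = X_u.reshape(0, X_l.shape[1])
    X_u = np.atleast_2d(X_u)

    n_u = len(X_u)
    entropy_tol = schedule.entropy_tol if schedule.entropy_tol is not None else 1e-6 * max(n_u, 1)

    if n_u == 0:
        model = weighted_train(X_l, y_l, X_u, np.empty(0), C=C, C_star=C_star)
        fe = free_energy(model, np.empty(0), schedule.T0, X_l, y_l, X_u, C, C_star)
        trace = [{"outer_step": 0, "T": schedule.T0, "inner_step": 0,
                  "free_energy_after_train": fe, "free_energy": fe,
                  "entropy": 0.0, "kl_prev": 0.0}]
        return DAState(model=model, p=np.empty(0), T=schedule.T0,
                       free_energy=fe, entropy=0.0, objective=fe, trace=trace)

    p = np.full(n_u, 0.5) if p_init is None else np.asarray(p_init, dtype=float).copy()
    trace: list[dict] = []
    best: DAState | None = None

    # The first subproblem warm-starts from the supervised solution on the
    # labeled set.  This also arms the monotone safeguard from the very
    # first block update: the duplicated subproblem at spatially uniform p
    # is dual-degenerate, and an SMO solution that fails to beat the
    # incumbent would otherwise be accepted and can lock the whole
    # homotopy into a w=0 fixed point.
    model: LinearModel = train_linear_svm(X_l, y_l, C=1.0,
                                          sample_weights=np.full(len(y_l), C))
    baseline = model
    for outer, T in enumerate(schedule.temperatures()):
        reseeded = False
        for inner in range(schedule.inner_max):
            candidate = weighted_train(X_l, y_l, X_u, p, C=C, C_star=C_star)
            fe_train = free_energy(candidate, p, T, X_l, y_l, X_u, C, C_star)
            # monotone safeguard: the solver is inexact at machine scale,
            # so keep the incumbent if the refit would raise the
            # objective at fixed p
            fe_old = free_energy(model, p, T, X_l, y_l, X_u, C, C_star)
            if fe_train > fe_old:
                fe_train = fe_old
            else:
                model = candidate
            p_new = update_soft_labels(model, X_u, T, C_star=C_star, balance=balance)
            if p_new.std() < 1e-6 and not reseeded:
                # Symmetry breaking.  Above the phase transition the
                # spatially uniform label distribution is a fixed point
                # (the incumbent hyperplane collapses, every g_j is equal
                # and the update returns identical p_j); the homotopy
                # would then carry no signal into the cold phase.  Re-seed
                # the labels once per temperature from the supervised
                # baseline's decision values, the DA analogue of
                # perturbing duplicate centroids in annealed clustering.
                p_new = update_soft_labels(baseline, X_u, T, C_star=C_star, balance=balance)
                reseeded = True
                reseed_step = True
            else:
                reseed_step = False
            kl = _sym_kl(p, p_new)
            p = p_new
            fe = free_energy(model, p, T, X_l, y_l, X_u, C, C_star)
            ent = float(np.sum(bernoulli_entropy(p)))
            if not np.isfinite(fe):
                raise FloatingPointError(
                    f"non-finite free energy at T={T}, inner step {inner}; trace length {len(trace)}"
                )
            obj = fe + T * ent  # E_p[F]: free energy without the -T*S term
            trace.append({"outer_step": outer, "T": T, "inner_step": inner,
                          "free_energy_after_train": fe_train,
                          "free_energy": fe, "entropy": ent, "kl_prev": kl,
                          "reseeded": reseed_step})
            if best is None or obj <= best.objective:
                best = DAState(model=model, p=p.copy(), T=T, free_energy=fe,
                               entropy=ent, objective=obj, trace=trace)
            if kl < schedule.inner_tol:
                break
        if ent < entropy_tol:
            break

    assert best is not None
    best.trace = trace
    return best


def write_trace(trace: list[dict], path) -> None:
    """Persist an annealing trace as TSV."""
    import pandas as pd

    pd.DataFrame(trace).to_csv(path, sep="\t", index=False)
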