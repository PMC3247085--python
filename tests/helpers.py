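"""Independent test oracles.

These deliberately avoid the code paths they check: the SVM oracle solves
the primal slack-variable quadratic program with a generic NLP solver,
the AUC oracle counts positive-negative pairs, the soft-label oracle does
per-coordinate grid search, and the query-selection oracle sorts scores
outright.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import LinearConstraint, minimize


def qp_svm(X, y, C=1.0, sample_weights=None):
    """Solve min 1/2||w||^2 + C * sum_i s_i xi_i  s.t. xi_i >= 0,
    xi_i >= 1 - y_i (w.x_i + b) as a generic convex QP (trust-constr on
    the primal with exact gradient/Hessian).  Returns (w, b)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    s = np.ones(n) if sample_weights is None else np.asarray(sample_weights, dtype=float)
    m = d + 1 + n  # z = [w, b, xi]

    H = np.zeros((m, m))
    H[:d, :d] = np.eye(d)
    c_lin = np.concatenate([np.zeros(d + 1), C * s])

    A = np.zeros((2 * n, m))
    A[:n, d + 1:] = np.eye(n)                      # xi >= 0
    A[n:, :d] = y[:, None] * X                     # y f(x) + xi >= 1
    A[n:, d] = y
    A[n:, d + 1:] = np.eye(n)
    lb = np.concatenate([np.zeros(n), np.ones(n)])

    z0 = np.zeros(m)
    z0[d + 1:] = 1.0
    res = minimize(
        lambda z: 0.5 * z @ H @ z + c_lin @ z,
        z0,
        jac=lambda z: H @ z + c_lin,
        hess=lambda z: H,
        method="trust-constr",
        constraints=[LinearConstraint(A, lb, np.inf)],
        options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 3000},
    )
    assert res.status in (1, 2), res.message
    w = res.x[:d]
    return w, _canonical_bias(X, y, C * s, w)


def _canonical_bias(X, y, c, w):
    """Midpoint of the optimal-intercept interval at fixed w.

    With every support vector at bound the hinge objective is flat in b
    over an interval and the QP solver may return any point of it; libsvm
    reports the interval midpoint, so the oracle canonicalizes the same
    way.  Exact scan of the piecewise-linear function
    h(b) = sum_i c_i max(0, 1 - y_i (x_i.w + b)).
    """
    f = X @ w
    bps = np.sort(y - f)  # kinks of h
    eps = 1e-9

    def slope(b):
        mask = y * (f + b) < 1.0
        return float(-np.sum(c[mask] * y[mask]))

    # first kink whose right-hand slope is non-negative
    for k, b in enumerate(bps):
        s_right = slope(b + eps)
        if s_right < -1e-12:
            continue  # still descending
        if s_right > 1e-12:
            # ascending to the right: minimum is this kink, or the flat
            # segment ending here
            if k > 0 and abs(slope(b - eps)) <= 1e-12:
                return float((bps[k - 1] + b) / 2)
            return float(b)
        # flat to the right: minimum spans [b, next kink]
        if k + 1 < len(bps):
            return float((b + bps[k + 1]) / 2)
        return float(b)
    return float(bps[-1])


def brute_force_auc(y_true, scores):
    """Mann-Whitney pair count: ties count one half."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y_true > 0]
    neg = scores[y_true < 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def grid_search_soft_labels(model, X_u, T, C_star=1.0, resolution=1e-4):
    """Per-coordinate minimization of the free energy in p by grid search."""
    from ppispotter.annealing import bernoulli_entropy
    from ppispotter.svm import decision_value

    f = np.atleast_1d(decision_value(model, X_u))
    grid = np.arange(0.0, 1.0 + resolution / 2, resolution)
    S = bernoulli_entropy(grid)
    out = np.empty(len(f))
    for j, fj in enumerate(f):
        h_pos = max(0.0, 1.0 - fj)
        h_neg = max(0.0, 1.0 + fj)
        vals = C_star * (grid * h_pos + (1 - grid) * h_neg) - T * S
        out[j] = grid[np.argmin(vals)]
    return out


def brute_force_select(p_pos, k):
    """Sort all |2P-1| scores (ties by index) and take the first k."""
    scores = [(abs(2 * p - 1), i) for i, p in enumerate(p_pos)]
    return [i for _, i in sorted(scores)[:k]]


def brute_force_gazetteer_count(tokens, gazetteer_entries):
    """Greedy longest-match count by direct enumeration over all entry
    token forms at every position."""
    from ppispotter.features import tokenize

    toks = [t.lower() for t in tokens]
    forms = sorted({tuple(tokenize(g)) for g in gazetteer_entries}, key=len, reverse=True)
    i, count = 0, 0
    while i < len(toks):
        for form in forms:
            if tuple(toks[i:i + len(form)]) == form:
                count += 1
                i += len(form)
                break
        else:
            i += 1
    return count
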