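"""Independent brute-force oracles used to validate the package's fast paths.

These deliberately avoid the implementations under test: Fisher p-values by
full hypergeometric enumeration, the Wakefield factor as an explicit ratio of
two normal densities, AUC by pair counting, and the weighted logistic MLE by
Newton-Raphson on the analytic gradient/Hessian.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy import stats


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by enumerating all tables with the observed margins
    and summing the probabilities of those no more probable than observed."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x: int) -> float:
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    cutoff = p_obs * (1.0 + 1e-12)  # guard against float noise on equal-prob tables
    return sum(prob(x) for x in range(min(r1, c1) + 1) if prob(x) <= cutoff)


def wakefield_density_ratio_oracle(beta_hat: float, se: float, prior_sd: float) -> float:
    """BF as the ratio of Normal(0, V+W) to Normal(0, V) densities at beta_hat."""
    V, W = se**2, prior_sd**2
    return stats.norm.pdf(beta_hat, 0.0, np.sqrt(V + W)) / stats.norm.pdf(beta_hat, 0.0, np.sqrt(V))


def auc_pair_oracle(scores, labels) -> float:
    """AUC by enumerating every (hit, non-hit) pair; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def newton_weighted_logistic_mle(X, y, w, max_iter: int = 200, tol: float = 1e-12) -> np.ndarray:
    """Weighted logistic MLE (intercept first) by Newton-Raphson."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    Xd = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xd.shape[1])
    for _ in range(max_iter):
        eta = Xd @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = Xd.T @ (w * (y - p))
        hess = (Xd * (w * p * (1 - p))[:, None]).T @ Xd
        step = np.linalg.solve(hess, grad)
        beta += step
        if np.abs(step).max() < tol:
            break
    return beta
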