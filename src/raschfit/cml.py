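"""Conditional maximum likelihood estimation of Rasch item difficulties.

Conditioning on the raw score eliminates the person parameters; the
conditional likelihood of a person with raw score r is

    P(x | r) = prod_i eps_i^{x_i} / gamma_r(eps),    eps_i = exp(-beta_i),

where gamma_r is the elementary symmetric function (ESF) of order r of the
easiness parameters eps. The conditional log-likelihood of the sample is

    ln L(beta) = -sum_i s_i beta_i - sum_r n_r ln gamma_r(eps)

with s_i the item totals and n_r the raw-score frequencies among persons
with non-extreme scores (0 < r < n). ESFs are evaluated with the summation
recursion, which is numerically stable for the test lengths used here
(up to about 50 items).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datagen import ResponseMatrix
from .exceptions import DegenerateDataError, NonConvergenceError

GRAD_TOL = 1e-8
MAX_ITER = 100


@dataclass
class CmlFit:
    """Result of a conditional maximum likelihood fit.

    beta_hat is normalized to sum zero; cond_loglik is the maximized
    conditional log-likelihood; score_counts[r] is the number of retained
    persons with raw score r; n_used counts persons after removing extreme
    scores (0 or n), which carry no conditional information.
    """

    beta_hat: np.ndarray
    cond_loglik: float
    score_counts: np.ndarray
    converged: bool
    n_used: int
    n_excluded: int


def elementary_symmetric(epsilon: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ESFs of all orders plus the per-item first derivatives.

    Returns (gamma, dgamma): gamma[r] is the order-r ESF for r = 0..n;
    dgamma[i, r] = d gamma_r / d eps_i, i.e. the order-(r-1) ESF of the
    vector with item i removed. Both are built with the summation
    recursion; the derivative table re-runs the recursion with one item
    left out (vectorized over the left-out item) rather than dividing out,
    which avoids the cancellation of the difference algorithm.
    """
    epsilon = np.asarray(epsilon, dtype=float)
    n = epsilon.size
    if n == 0 or np.any(epsilon <= 0) or not np.all(np.isfinite(epsilon)):
        raise ValueError("epsilon must be a nonempty vector of positive finite reals")
    gamma = np.zeros(n + 1)
    gamma[0] = 1.0
    # leave-one-out ESF table: row i excludes item i
    G = np.zeros((n, n + 1))
    G[:, 0] = 1.0
    for j in range(n):
        gamma[1:] += epsilon[j] * gamma[:-1]
        rows = np.arange(n) != j
        G[rows, 1:] += epsilon[j] * G[rows, :-1]
    # dgamma[i, r] = gamma_{r-1}^{(i)}
    dgamma = np.zeros((n, n + 1))
    dgamma[:, 1:] = G[:, :-1]
    return gamma, dgamma


def _neg_cond_loglik(beta: np.ndarray, s: np.ndarray, n_r: np.ndarray):
    """Negative conditional log-likelihood and gradient.

    n_r has length n + 1 indexed by raw score; extreme scores must be 0.
    """
    eps = np.exp(-beta)
    gamma, dgamma = elementary_symmetric(eps)
    ll = -float(s @ beta) - float(n_r[1:-1] @ np.log(gamma[1:-1]))
    # d lnL / d beta_i = -s_i + sum_r n_r * eps_i * gamma_{r-1}^{(i)} / gamma_r
    expected = eps[:, None] * dgamma[:, 1:-1] / gamma[None, 1:-1]
    grad = -s + expected @ n_r[1:-1]
    return -ll, -grad


def _neg_cond_hessian(beta: np.ndarray, n_r: np.ndarray) -> np.ndarray:
    """Hessian of the negative conditional log-likelihood.

    Equals the sum over raw scores r of n_r times the conditional covariance
    matrix of the response vector given score r:

        H_ii = sum_r n_r E_i(r) (1 - E_i(r))
        H_ik = sum_r n_r (E_ik(r) - E_i(r) E_k(r))

    with E_i(r) = eps_i gamma_{r-1}^{(i)} / gamma_r the conditional solve
    probability and E_ik(r) = eps_i eps_k gamma_{r-2}^{(i,k)} / gamma_r the
    conditional pair probability. Pair-deleted ESFs are obtained by a
    one-step downdate of the item-deleted table; the resulting Hessian is
    only used as a step direction, where the downdate's mild cancellation
    is harmless.
    """
    eps = np.exp(-beta)
    n = eps.size
    gamma, dgamma = elementary_symmetric(eps)
    G = dgamma[:, 1:]  # G[i, r] = gamma_r^{(i)}, r = 0..n-1
    w = n_r[1:-1]      # weights for scores r = 1..n-1
    E = eps[:, None] * G[:, :-1] / gamma[None, 1:-1]  # E[i, r-1] = E_i(r)
    H = np.zeros((n, n))
    np.fill_diagonal(H, (E * (1.0 - E)) @ w)
    small = eps <= 1.0
    for i in range(n):
        # D[k, r] = gamma_r^{(i,k)} by downdating gamma^{(i)}; run the
        # recursion forward for eps_k <= 1 and backward (dividing by eps_k)
        # for eps_k > 1, so rounding errors are damped in either direction
        D = np.zeros((n, n - 1))
        D[:, 0] = 1.0
        for r in range(1, n - 1):
            D[small, r] = G[i, r] - eps[small] * D[small, r - 1]
        if not small.all():
            big = ~small
            if n >= 3:
                D[big, n - 2] = G[i, n - 1] / eps[big]
                for r in range(n - 2, 0, -1):
                    D[big, r - 1] = (G[i, r] - D[big, r]) / eps[big]
        # E2[k, r-1] = E_ik(r), zero for r = 1
        E2 = np.zeros((n, n - 1))
        E2[:, 1:] = eps[i] * eps[:, None] * D[:, : n - 2] / gamma[None, 2:-1]
        off = (E2 - E[i][None, :] * E) @ w
        H[i, :] += off
        H[i, i] -= off[i]
    return 0.5 * (H + H.T)


def fit_cml(X: ResponseMatrix) -> CmlFit:
    """Fit Rasch item difficulties by conditional maximum likelihood.

    Persons with raw score 0 or n are excluded (their conditional likelihood
    is 1). Every retained item column must contain both responses. The
    optimum is found by damped Newton iteration with the analytic gradient
    and Hessian; convergence requires a gradient max-norm below 1e-8 within
    100 iterations.
    """
    data = X.data
    n = X.n_items
    scores = data.sum(axis=1)
    keep = (scores > 0) & (scores < n)
    retained = data[keep]
    n_used = int(keep.sum())
    if n_used == 0:
        raise DegenerateDataError("no persons with non-extreme raw scores")
    totals = retained.sum(axis=0)
    for i in range(n):
        if totals[i] == 0 or totals[i] == n_used:
            raise DegenerateDataError(
                f"item {X.items[i]!r} (column {i}) is constant among retained persons"
            )
    score_counts = np.bincount(retained.sum(axis=1), minlength=n + 1).astype(int)
    s = totals.astype(float)

    n_r = score_counts.astype(float)
    # damped Newton from the centered log-odds start; the all-ones shift
    # direction is flat, so it is penalized to keep the system well posed
    x = np.log((n_used - s) / s)
    x -= x.mean()
    ones = np.ones(n) / np.sqrt(n)
    f, g = _neg_cond_loglik(x, s, n_r)
    grad_max = float(np.max(np.abs(g)))
    for _ in range(MAX_ITER):
        if grad_max <= GRAD_TOL:
            break
        H = _neg_cond_hessian(x, n_r) + np.outer(ones, ones)
        step = np.linalg.solve(H, g)
        # step-halving: accept on a likelihood decrease or, near the
        # optimum where f-differences sink into rounding, on a gradient
        # decrease
        t = 1.0
        for _ in range(40):
            f_new, g_new = _neg_cond_loglik(x - t * step, s, n_r)
            if f_new <= f or float(np.max(np.abs(g_new))) <= grad_max:
                break
            t *= 0.5
        x = x - t * step
        f, g = f_new, g_new
        grad_max = float(np.max(np.abs(g)))
    if grad_max > GRAD_TOL:
        raise NonConvergenceError(
            f"CML fit did not converge: gradient max-norm {grad_max:.2e}",
            last_params=x,
        )
    beta_hat = x - x.mean()
    loglik = -_neg_cond_loglik(beta_hat, s, score_counts.astype(float))[0]
    return CmlFit(
        beta_hat=beta_hat,
        cond_loglik=float(loglik),
        score_counts=score_counts,
        converged=grad_max <= GRAD_TOL,
        n_used=n_used,
        n_excluded=int(X.n_persons - n_used),
    )


def cond_loglik(beta: np.ndarray, X: ResponseMatrix) -> float:
    """Conditional log-likelihood of X at an arbitrary difficulty vector."""
    data = X.data
    n = X.n_items
    scores = data.sum(axis=1)
    keep = (scores > 0) & (scores < n)
    retained = data[keep]
    s = retained.sum(axis=0).astype(float)
    n_r = np.bincount(retained.sum(axis=1), minlength=n + 1).astype(float)
    return -_neg_cond_loglik(np.asarray(beta, dtype=float), s, n_r)[0]
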