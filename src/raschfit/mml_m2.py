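"""Marginal maximum likelihood Rasch estimation and the M2 statistic.

The Rasch model is fit by MML with a normal ability distribution: slopes
are fixed at 1, the ability mean at 0, and the n item difficulties plus the
latent standard deviation are free, giving q = n + 1 parameters. The
marginal likelihood is maximized by an EM algorithm over a Gauss-Hermite
quadrature grid (61 nodes by default).

M2 is the limited-information overall fit statistic built from the first-
and second-order moments of the multivariate Bernoulli distribution of the
n response indicators:

    M2 = N (p2 - pi2)' C (p2 - pi2)
    C  = Xi^-1 - Xi^-1 D (D' Xi^-1 D)^-1 D' Xi^-1

where p2 / pi2 stack the s = n + n(n-1)/2 observed / model-implied moments,
Xi is the asymptotic covariance of the sample moments (assembled from
model-implied moments up to order 4), and D is the Jacobian of pi2 in the
parameters. M2 is chi-square with s - q degrees of freedom under the model.
The quadratic form is evaluated on an orthonormal basis of the null space
of D', which is algebraically equal to the C form but numerically stabler.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.linalg import cho_factor, cho_solve, null_space
from scipy.special import expit, logsumexp
from scipy.stats import chi2

from .datagen import ResponseMatrix
from .exceptions import DegenerateDataError, NonConvergenceError
from .lr_test import TestResult

N_QUAD = 61
EM_TOL = 1e-5
EM_MAX_CYCLES = 500


def _quad_nodes(n_quad: int = N_QUAD) -> tuple[np.ndarray, np.ndarray]:
    """Standard normal quadrature nodes and weights (probabilists' GH)."""
    z, w = hermegauss(n_quad)
    return z, w / w.sum()


@dataclass
class MmlFit:
    """MML fit of the Rasch model with free latent variance.

    beta_hat are the item difficulties, latent_sd the ability standard
    deviation (mean fixed at 0, slopes at 1), marg_loglik the maximized
    marginal log-likelihood, q = n + 1 the free-parameter count.
    """

    beta_hat: np.ndarray
    latent_sd: float
    marg_loglik: float
    nodes: np.ndarray
    weights: np.ndarray
    converged: bool
    n_cycles: int
    loglik_trace: np.ndarray

    @property
    def q(self) -> int:
        return self.beta_hat.size + 1

    def probs(self) -> np.ndarray:
        """(K, n) matrix of response probabilities at the quadrature nodes."""
        theta = self.latent_sd * self.nodes
        return expit(theta[:, None] - self.beta_hat[None, :])


def fit_mml(X: ResponseMatrix, n_quad: int = N_QUAD,
            tol: float = EM_TOL, max_cycles: int = EM_MAX_CYCLES) -> MmlFit:
    """EM estimation of (beta, latent_sd) from dichotomous responses.

    Convergence is declared when the largest absolute parameter change in a
    cycle falls below ``tol`` (default 1e-5) within ``max_cycles`` (default
    500) cycles. The M-step is iterated to an interior optimum, so the
    marginal log-likelihood is non-decreasing across cycles.
    """
    data = X.data.astype(float)
    N, n = data.shape
    totals = data.sum(axis=0)
    if np.any(totals == 0) or np.any(totals == N):
        bad = int(np.argmax((totals == 0) | (totals == N)))
        raise DegenerateDataError(
            f"item {X.items[bad]!r} (column {bad}) is constant; MML fit undefined"
        )
    z, w = _quad_nodes(n_quad)

    pbar = totals / N
    beta = np.log((1.0 - pbar) / pbar)
    sigma = 1.0
    trace = []

    for cycle in range(1, max_cycles + 1):
        # E-step: posterior over nodes per person
        P = expit(sigma * z[:, None] - beta[None, :])  # (K, n)
        logP = np.log(P)
        log1P = np.log1p(-P)
        loglik_jk = data @ logP.T + (1.0 - data) @ log1P.T  # (N, K)
        log_joint = loglik_jk + np.log(w)[None, :]
        ll = float(logsumexp(log_joint, axis=1).sum())
        trace.append(ll)
        post = np.exp(log_joint - logsumexp(log_joint, axis=1, keepdims=True))
        n_k = post.sum(axis=0)              # (K,) expected persons per node
        R = post.T @ data                   # (K, n) expected positives per node

        # M-step: Newton iterations on beta and sigma to the inner optimum
        beta_new, sigma_new = beta.copy(), sigma
        for _ in range(50):
            P = expit(sigma_new * z[:, None] - beta_new[None, :])
            V = n_k[:, None] * P * (1.0 - P)
            f = (R - n_k[:, None] * P).sum(axis=0)          # dQ/dbeta = -f
            beta_step = f / V.sum(axis=0)
            beta_new = beta_new - beta_step
            P = expit(sigma_new * z[:, None] - beta_new[None, :])
            V = n_k[:, None] * P * (1.0 - P)
            g = float((z[:, None] * (R - n_k[:, None] * P)).sum())
            h = float((z[:, None] ** 2 * V).sum())
            sigma_step = g / h
            sigma_new = float(np.clip(sigma_new + sigma_step, 1e-3, 10.0))
            if max(np.max(np.abs(beta_step)), abs(sigma_step)) < 1e-10:
                break

        delta = max(float(np.max(np.abs(beta_new - beta))), abs(sigma_new - sigma))
        beta, sigma = beta_new, sigma_new
        if delta < tol:
            return MmlFit(beta_hat=beta, latent_sd=sigma, marg_loglik=trace[-1],
                          nodes=z, weights=w, converged=True, n_cycles=cycle,
                          loglik_trace=np.array(trace))
    raise NonConvergenceError(
        f"EM did not converge within {max_cycles} cycles (last change {delta:.2e})",
        last_params=np.append(beta, sigma),
    )


def _order2_sets(n: int) -> list[tuple[int, ...]]:
    return [(i,) for i in range(n)] + list(itertools.combinations(range(n), 2))


def subset_moment(P: np.ndarray, w: np.ndarray, subset: tuple[int, ...]) -> float:
    """E[prod_{i in subset} X_i] by quadrature (local independence given theta)."""
    return float(w @ np.prod(P[:, subset], axis=1))


def model_moments(fit: MmlFit, subsets: list[tuple[int, ...]] | None = None) -> np.ndarray:
    """Model-implied joint moments; defaults to all moments up to order 2."""
    P = fit.probs()
    if subsets is None:
        subsets = _order2_sets(fit.beta_hat.size)
    return np.array([subset_moment(P, fit.weights, A) for A in subsets])


def sample_moments(X: ResponseMatrix) -> np.ndarray:
    """Observed first- and second-order moment vector p2."""
    data = X.data.astype(float)
    N, n = data.shape
    cross = (data.T @ data) / N
    singles = np.diag(cross)
    pairs = [cross[i, j] for i, j in itertools.combinations(range(n), 2)]
    return np.concatenate([singles, pairs])


def _jacobian(fit: MmlFit, sets: list[tuple[int, ...]]) -> np.ndarray:
    """s x (n+1) Jacobian of model moments in (beta_1..n, latent_sd)."""
    P = fit.probs()
    w, z = fit.weights, fit.nodes
    n = fit.beta_hat.size
    D = np.zeros((len(sets), n + 1))
    for a, A in enumerate(sets):
        prod = np.prod(P[:, A], axis=1)  # (K,)
        one_minus = 1.0 - P[:, A]        # (K, |A|)
        for col, i in enumerate(A):
            # dP_i/dbeta_i = -P_i(1-P_i); product keeps the other factors
            D[a, i] = -float(w @ (prod * one_minus[:, col]))
        # dP_i/dsigma = z * P_i(1-P_i)
        D[a, n] = float(w @ (prod * (z * one_minus.sum(axis=1))))
    return D


def _xi_matrix(fit: MmlFit, sets: list[tuple[int, ...]]) -> np.ndarray:
    """Asymptotic covariance of the sample moments at the fitted model."""
    P = fit.probs()
    w = fit.weights
    unions: dict[tuple[int, ...], float] = {}

    def union_moment(A, B):
        U = tuple(sorted(set(A) | set(B)))
        if U not in unions:
            unions[U] = subset_moment(P, w, U)
        return unions[U]

    mom = np.array([subset_moment(P, w, A) for A in sets])
    s = len(sets)
    Xi = np.empty((s, s))
    for a in range(s):
        for b in range(a, s):
            Xi[a, b] = Xi[b, a] = union_moment(sets[a], sets[b]) - mom[a] * mom[b]
    return Xi


def m2_statistic(X: ResponseMatrix, fit: MmlFit) -> TestResult:
    """M2 overall fit statistic with df = s - q.

    Evaluated in the orthogonal complement of the Jacobian column space:
    M2 = N e' U (U' Xi U)^-1 U' e with U an orthonormal null-space basis of
    D' and e = p2 - pi2.
    """
    n = X.n_items
    sets = _order2_sets(n)
    s = len(sets)
    q = fit.q
    if s <= q:
        raise ValueError(f"s = {s} moments cannot identify q = {q} parameters")
    e = sample_moments(X) - model_moments(fit)
    D = _jacobian(fit, sets)
    if np.linalg.matrix_rank(D) < q:
        raise np.linalg.LinAlgError("moment Jacobian is rank deficient")
    U = null_space(D.T)
    if U.shape[1] != s - q:
        raise np.linalg.LinAlgError(
            f"null space dimension {U.shape[1]} != s - q = {s - q}"
        )
    Xi = _xi_matrix(fit, sets)
    A = U.T @ Xi @ U
    try:
        chol = cho_factor(A)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"projected moment covariance not invertible (cond {np.linalg.cond(A):.2e})"
        ) from err
    v = U.T @ e
    stat = float(X.n_persons * (v @ cho_solve(chol, v)))
    stat = max(stat, 0.0)
    df = s - q
    p = float(chi2.sf(stat, df))
    return TestResult(
        statistic=stat,
        df=df,
        p_value=max(p, np.finfo(float).tiny),
        method="M2",
        diagnostics={
            "s": s,
            "q": q,
            "latent_sd": fit.latent_sd,
            "converged": fit.converged,
            "n_persons_used": X.n_persons,
            "n_items_used": n,
        },
    )


def m2_statistic_cform(X: ResponseMatrix, fit: MmlFit) -> float:
    """M2 via the explicit C = Xi^-1 - Xi^-1 D (D'Xi^-1 D)^-1 D'Xi^-1 form.

    Kept as an independent algebraic route for cross-checking the
    null-space evaluation on small item sets.
    """
    n = X.n_items
    sets = _order2_sets(n)
    e = sample_moments(X) - model_moments(fit)
    D = _jacobian(fit, sets)
    Xi = _xi_matrix(fit, sets)
    Xi_inv = np.linalg.inv(Xi)
    middle = np.linalg.inv(D.T @ Xi_inv @ D)
    C = Xi_inv - Xi_inv @ D @ middle @ D.T @ Xi_inv
    return float(X.n_persons * e @ C @ e)
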