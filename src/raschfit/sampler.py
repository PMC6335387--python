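"""Uniform sampling of 0/1 matrices with fixed row and column sums.

The reference set for the nonparametric tests is the collection of binary
matrices sharing the observed margins. A rectangle-swap Markov chain walks
on this set: pick two rows and two columns uniformly at random; if the
2x2 submatrix is a checkerboard ([[1,0],[0,1]] or [[0,1],[1,0]]), flip it,
otherwise stay. The proposal is symmetric and the chain is connected and
aperiodic on the margin-fixed set, so its stationary distribution is
uniform. States are retained every ``thin`` proposals after ``burn_in``
proposals.

Default chain lengths scale with the number of ones m in the matrix:
burn_in = 100 m proposals, thin = 2 m proposals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .datagen import ResponseMatrix

# proposals drawn per kernel call; bounds memory for long chains
_CHUNK = 1 << 18


@dataclass
class MarginFixedSample:
    """B retained draws from the margin-fixed reference set.

    ``singleton`` flags a source matrix without any swappable checkerboard,
    whose reference set contains only the matrix itself (every bootstrap
    p-value is then 1).
    """

    matrices: np.ndarray  # (B, N, n) int8
    burn_in: int
    thin: int
    seed: object = None
    singleton: bool = False

    @property
    def B(self) -> int:
        return self.matrices.shape[0]


@njit(cache=False)
def _run_chunk(X, r1, r2, c1, c2):
    """Apply one chunk of rectangle-swap proposals in place."""
    for t in range(r1.size):
        a = r1[t]
        b = r2[t]
        c = c1[t]
        d = c2[t]
        x11 = X[a, c]
        x12 = X[a, d]
        x21 = X[b, c]
        x22 = X[b, d]
        if x11 == x22 and x12 == x21 and x11 != x12:
            X[a, c] = x12
            X[a, d] = x11
            X[b, c] = x22
            X[b, d] = x21


def _advance_chain(X: np.ndarray, n_proposals: int, rng: np.random.Generator) -> None:
    N, n = X.shape
    done = 0
    while done < n_proposals:
        k = min(_CHUNK, n_proposals - done)
        r = rng.integers(0, N, size=(2, k))
        c = rng.integers(0, n, size=(2, k))
        _run_chunk(X, r[0], r[1], c[0], c[1])
        done += k


def has_checkerboard(data: np.ndarray) -> bool:
    """True if any 2x2 checkerboard submatrix exists (reference set > 1)."""
    X = data.astype(np.int64)
    both = X.T @ (1 - X)  # count of (1,0) patterns per ordered column pair
    np.fill_diagonal(both, 0)
    return bool(np.any((both > 0) & (both.T > 0)))


def sample_fixed_margins(X: ResponseMatrix, B: int, burn_in: int | None = None,
                         thin: int | None = None,
                         rng: np.random.Generator | None = None) -> MarginFixedSample:
    """Draw B matrices uniformly from the margin-fixed reference set of X.

    burn_in and thin default to 100x and 2x the number of ones in X,
    counted in proposals. Row and column sums of every draw equal those of
    X exactly (integer arithmetic; swaps conserve margins).
    """
    if B < 1:
        raise ValueError("B must be positive")
    if rng is None:
        rng = np.random.default_rng()
    m = int(X.data.sum())
    if burn_in is None:
        burn_in = 100 * m
    if thin is None:
        thin = 2 * m
    if burn_in < 0:
        raise ValueError("burn_in must be nonnegative")
    if thin < 1:
        raise ValueError("thin must be positive")

    if not has_checkerboard(X.data):
        mats = np.repeat(X.data[None, :, :], B, axis=0)
        return MarginFixedSample(matrices=mats, burn_in=burn_in, thin=thin,
                                 singleton=True)

    state = X.data.copy()
    out = np.empty((B, X.n_persons, X.n_items), dtype=np.int8)
    _advance_chain(state, burn_in, rng)
    for b in range(B):
        _advance_chain(state, thin, rng)
        out[b] = state
    return MarginFixedSample(matrices=out, burn_in=burn_in, thin=thin)
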