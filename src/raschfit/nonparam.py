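"""Ponocny's nonparametric T10 and T11 statistics with bootstrap p-values.

T10 (subgroup invariance, a first-order statistic):

    T10 = sum_{i<j} | N_ij(h) N_ji(l) - N_ij(l) N_ji(h) |

where N_ij(h) counts persons answering item i positively and item j
negatively whose raw score is at least the median, and N_ij(l) the same for
below-median persons.

T11 (local dependence, a second-order statistic):

    T11 = sum_{i<j} | r_ij - rho_ij |

with r_ij the observed inter-item (phi) correlation and rho_ij its expected
value under the Rasch null, estimated as the mean correlation over the
margin-fixed bootstrap sample. Both statistics are referred to their
distribution over that same sample; because the sampler preserves row sums,
the median score split is identical for every draw.
"""

from __future__ import annotations

import numpy as np

from .datagen import ResponseMatrix
from .exceptions import DegenerateDataError
from .lr_test import ScoreGroupSplit, TestResult, median_split
from .sampler import sample_fixed_margins


def _pair_counts(data: np.ndarray) -> np.ndarray:
    """counts[i, j] = number of rows with item i = 1 and item j = 0."""
    X = data.astype(np.int64)
    ones = X.sum(axis=0)
    return ones[:, None] - X.T @ X


def t10_statistic(X: ResponseMatrix | np.ndarray, split: ScoreGroupSplit) -> float:
    """T10 for a matrix under a fixed high/low score split."""
    data = X.data if isinstance(X, ResponseMatrix) else np.asarray(X)
    g = split.group_of_person
    Nh = _pair_counts(data[g == 1])
    Nl = _pair_counts(data[g == 0])
    diff = np.abs(Nh * Nl.T - Nl * Nh.T)
    return float(np.triu(diff, k=1).sum())


def _phi_matrix(data: np.ndarray) -> np.ndarray:
    col_sd = data.std(axis=0)
    if np.any(col_sd == 0):
        bad = int(np.argmax(col_sd == 0))
        raise DegenerateDataError(f"item column {bad} is constant; phi undefined")
    return np.corrcoef(data, rowvar=False)


def t11_statistic(X: ResponseMatrix | np.ndarray, rho_null: np.ndarray) -> float:
    """T11: aggregate deviation of observed phi correlations from the null mean."""
    data = X.data if isinstance(X, ResponseMatrix) else np.asarray(X)
    r = _phi_matrix(data)
    return float(np.triu(np.abs(r - rho_null), k=1).sum())


def nonparam_test(X: ResponseMatrix, which: str, B: int = 500,
                  burn_in: int | None = None, thin: int | None = None,
                  rng: np.random.Generator | None = None) -> TestResult:
    """Bootstrap p-value for T10 or T11 over the margin-fixed reference set.

    p = (1 + #{draws with statistic >= observed}) / (B + 1); the add-one
    form counts the observed matrix as one member of its own reference set
    and avoids zero p-values. If the reference set is a singleton the
    p-value is 1 and the result is flagged.
    """
    which = which.upper()
    if which not in ("T10", "T11"):
        raise ValueError("which must be 'T10' or 'T11'")
    sample = sample_fixed_margins(X, B=B, burn_in=burn_in, thin=thin, rng=rng)

    if which == "T10":
        split = median_split(X)
        # row sums are conserved, so the observed split applies to all draws
        assert np.array_equal(sample.matrices[0].sum(axis=1), X.raw_scores())
        obs = t10_statistic(X, split)
        null_stats = np.array([t10_statistic(m, split) for m in sample.matrices])
    else:
        corr = np.array([_phi_matrix(m) for m in sample.matrices])
        rho_null = corr.mean(axis=0)
        obs = t11_statistic(X, rho_null)
        null_stats = np.array([
            float(np.triu(np.abs(c - rho_null), k=1).sum()) for c in corr
        ])

    if sample.singleton:
        p = 1.0
    else:
        p = (1.0 + float(np.sum(null_stats >= obs))) / (B + 1.0)
    return TestResult(
        statistic=obs,
        df=None,
        p_value=p,
        method=which,
        diagnostics={
            "B": sample.B,
            "burn_in": sample.burn_in,
            "thin": sample.thin,
            "singleton": sample.singleton,
            "n_persons_used": X.n_persons,
            "n_items_used": X.n_items,
        },
    )
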