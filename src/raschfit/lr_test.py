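"""Andersen's conditional likelihood-ratio test.

The sample is split into score groups (here: below vs at-least-median raw
score); the statistic

    LR = 2 * ( sum_c ln L_c(beta_hat_c)  -  ln L(beta_hat) )

compares the group-wise conditional maximum likelihood fits with the
total-sample fit and is asymptotically chi-square with degrees of freedom
equal to the number of parameters estimated across groups minus the number
estimated in the total sample (n' - 1 for two groups on a common item set
of size n').
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .cml import fit_cml
from .datagen import ResponseMatrix
from .exceptions import DegenerateDataError, DegenerateSplitError


@dataclass
class ScoreGroupSplit:
    """Assignment of persons to score groups.

    group_of_person holds one label per row of the source matrix: -1 for
    persons excluded for an extreme raw score, otherwise 0..G-1.
    """

    group_of_person: np.ndarray
    G: int
    rule: str

    def __post_init__(self):
        self.group_of_person = np.asarray(self.group_of_person, dtype=int)
        labels = self.group_of_person[self.group_of_person >= 0]
        if labels.size == 0:
            raise DegenerateSplitError("no persons assigned to any group")
        counts = np.bincount(labels, minlength=self.G)
        if self.G < 2 or np.any(counts == 0):
            raise DegenerateSplitError("every score group must be nonempty")


@dataclass
class TestResult:
    """Outcome of one goodness-of-fit test.

    df is None for the nonparametric (bootstrap) tests, which have no
    asymptotic reference distribution.
    """

    statistic: float
    df: int | None
    p_value: float
    method: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.statistic < 0:
            raise ValueError("statistic must be nonnegative")
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value must lie in (0, 1]")

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            **{k: v for k, v in self.diagnostics.items()
               if np.isscalar(v) or v is None},
        }


def median_split(X: ResponseMatrix) -> ScoreGroupSplit:
    """Two score groups around the median raw score.

    Persons with extreme raw scores (0 or n) are excluded before the median
    is taken. Persons scoring at least the median go to the high group
    (label 1), the rest to the low group (label 0).
    """
    scores = X.raw_scores()
    keep = (scores > 0) & (scores < X.n_items)
    if not keep.any():
        raise DegenerateSplitError("all persons have extreme raw scores")
    med = float(np.median(scores[keep]))
    labels = np.full(X.n_persons, -1, dtype=int)
    labels[keep] = (scores[keep] >= med).astype(int)
    if not (labels == 0).any() or not (labels == 1).any():
        raise DegenerateSplitError(
            "median split left one group empty (raw scores too concentrated)"
        )
    return ScoreGroupSplit(group_of_person=labels, G=2,
                           rule="raw score >= median -> high group; extremes excluded")


def _submatrix(X: ResponseMatrix, rows: np.ndarray, cols: np.ndarray) -> ResponseMatrix:
    return ResponseMatrix(
        data=X.data[np.ix_(rows, cols)],
        persons=[X.persons[j] for j in np.flatnonzero(rows)],
        items=[X.items[i] for i in np.flatnonzero(cols)],
    )


def andersen_lr(X: ResponseMatrix, split: ScoreGroupSplit) -> TestResult:
    """Andersen LR test over the given score-group split.

    Items that are constant within any group (or overall) are removed from
    all fits so the group parameter spaces remain nested within the total
    one; dropped items are recorded in the diagnostics and the degrees of
    freedom shrink accordingly.
    """
    n = X.n_items
    use = np.ones(n, dtype=bool)
    groups = [split.group_of_person == c for c in range(split.G)]
    all_retained = split.group_of_person >= 0

    dropped: list[str] = []
    for _ in range(n):
        if use.sum() < 2:
            raise DegenerateDataError("fewer than 2 items remain after drops")
        try:
            total_fit = fit_cml(_submatrix(X, all_retained, use))
            group_fits = [fit_cml(_submatrix(X, g, use)) for g in groups]
        except DegenerateDataError as err:
            # the error names the item; locate and drop it from all fits
            cols = np.flatnonzero(use)
            bad = next(
                (i for i in cols if f"{X.items[i]!r}" in str(err)), None
            )
            if bad is None:
                raise
            use[bad] = False
            dropped.append(X.items[bad])
            continue
        break
    else:
        raise DegenerateDataError("could not find a common non-degenerate item set")

    n_used = int(use.sum())
    stat = 2.0 * (sum(f.cond_loglik for f in group_fits) - total_fit.cond_loglik)
    if stat < -1e-6:
        raise RuntimeError(f"negative LR statistic {stat:.3e} beyond tolerance")
    stat = max(stat, 0.0)
    df = (split.G - 1) * (n_used - 1)
    p = float(chi2.sf(stat, df))
    return TestResult(
        statistic=float(stat),
        df=df,
        p_value=max(p, np.finfo(float).tiny),
        method="LR",
        diagnostics={
            "n_items_used": n_used,
            "n_persons_used": total_fit.n_used,
            "items_dropped": dropped,
            "converged": all(f.converged for f in [total_fit, *group_fits]),
        },
    )
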