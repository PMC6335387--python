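"""Monte-Carlo type-I-error and power study over condition grids.

Each condition fixes a sample size N, test length n, generating model and
replication count. Item parameters are drawn once per condition; abilities
(and latent classes) are redrawn every replication. Every requested test is
run on every replication and its p-value compared with the nominal alpha
levels; replications where a test errors out (degenerate data,
non-convergence) are excluded from that test's denominator and counted as
failures.

Seeding is hierarchical: a condition's seed spawns one stream for the item
draw and one per replication, so results are reproducible and independent
of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datagen import GeneratingModelSpec, items_for_spec, simulate_matrix
from .exceptions import DegenerateDataError, NonConvergenceError
from .lr_test import andersen_lr, median_split
from .mml_m2 import fit_mml, m2_statistic
from .nonparam import nonparam_test

KNOWN_TESTS = ("LR", "T10", "T11", "M2")


@dataclass
class SimulationCondition:
    """One cell of the study design."""

    N: int
    n: int
    spec: GeneratingModelSpec
    reps: int = 500
    alphas: tuple = (0.05, 0.01)
    seed: int = 0
    bootstrap: int = 300  # nonparametric B inside grids; 500 for single datasets

    def __post_init__(self):
        if self.reps < 1:
            raise ValueError("reps must be positive")
        if any(not 0 < a < 1 for a in self.alphas):
            raise ValueError("alpha levels must lie in (0, 1)")

    def key(self) -> tuple:
        return (self.N, self.n, tuple(sorted(self.spec.to_dict().items())), self.seed)

    def label(self) -> str:
        return f"{self.spec.family}/N={self.N}/n={self.n}"


def _run_test(test: str, X, bootstrap: int, rng) -> float:
    if test == "LR":
        return andersen_lr(X, median_split(X)).p_value
    if test == "M2":
        return m2_statistic(X, fit_mml(X)).p_value
    if test in ("T10", "T11"):
        return nonparam_test(X, which=test, B=bootstrap, rng=rng).p_value
    raise ValueError(f"unknown test {test!r}")


def run_condition(cond: SimulationCondition, tests=("LR",)) -> pd.DataFrame:
    """Rejection rates for one condition, one row per test x alpha."""
    for t in tests:
        if t not in KNOWN_TESTS:
            raise ValueError(f"unknown test {t!r}; expected subset of {KNOWN_TESTS}")
    ss = np.random.SeedSequence(cond.seed)
    item_ss, *rep_ss = ss.spawn(cond.reps + 1)
    items = items_for_spec(cond.spec, cond.n, np.random.default_rng(item_ss))

    pvals: dict[str, list[float]] = {t: [] for t in tests}
    failures: dict[str, int] = {t: 0 for t in tests}
    for r in range(cond.reps):
        rng = np.random.default_rng(rep_ss[r])
        X = simulate_matrix(cond.spec, cond.N, items, rng)
        for t in tests:
            try:
                pvals[t].append(_run_test(t, X, cond.bootstrap, rng))
            except (DegenerateDataError, NonConvergenceError, np.linalg.LinAlgError):
                failures[t] += 1

    rows = []
    for t in tests:
        p = np.array(pvals[t])
        n_ok = p.size
        for alpha in cond.alphas:
            count = int(np.sum(p < alpha)) if n_ok else 0
            rate = count / n_ok if n_ok else np.nan
            mcse = float(np.sqrt(rate * (1 - rate) / n_ok)) if n_ok else np.nan
            rows.append({
                "family": cond.spec.family,
                "condition": cond.label(),
                "N": cond.N,
                "n": cond.n,
                "test": t,
                "alpha": alpha,
                "rejections": count,
                "rate": rate,
                "mcse": mcse,
                "reps_used": n_ok,
                "failures": failures[t],
                "seed": cond.seed,
            })
    return pd.DataFrame(rows)


def run_grid(conditions, tests=("LR",)) -> pd.DataFrame:
    """Run a list of conditions serially; deterministic given each seed."""
    keys = [c.key() for c in conditions]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate condition keys in grid")
    frames = [run_condition(c, tests=tests) for c in conditions]
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
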