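"""Data generation for the Rasch model and five violation models.

All generators share the Rasch item response function

    P(X_ji = 1 | theta_j, beta_i) = exp(theta_j - beta_i) / (1 + exp(theta_j - beta_i))

and extend it per family:

``rasch``        standard normal abilities, unit slopes, zero lower asymptote.
``surface_ld``   Rasch data post-processed so that a prerequisite item is
                 overwritten to positive for most persons solving the
                 dependent item (surface local dependence); the two special
                 items carry difficulties -0.626 and 0.184.
``multidim``     two correlated standard normal traits, each driving one half
                 of the item set.
``mixed_rasch``  a latent class (proportion 0.40) for which the difficulties
                 of the first 20% or 40% of items are shifted by -0.8 (DIF).
``twopl``        item discriminations drawn from a log-normal distribution
                 (log-mean 0, log-variance 0.09 or 0.25).
``guessing``     constant pseudo-guessing lower asymptote (0.1 or 0.25):
                 P = gamma + (1 - gamma) * logistic(theta - beta).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

FAMILIES = ("rasch", "surface_ld", "multidim", "mixed_rasch", "twopl", "guessing")


@dataclass
class ItemParameters:
    """Per-item parameters of the generating model.

    beta       difficulty (logit scale)
    alpha      discrimination, > 0 (all 1 under the Rasch model)
    gamma      lower asymptote in [0, 1) (0 under the Rasch model)
    dimension  trait index in {1, 2} per item (all 1 unless two-dimensional)
    dif_shift  additive difficulty shift applied in the latent DIF class
    """

    beta: np.ndarray
    alpha: np.ndarray = None
    gamma: np.ndarray = None
    dimension: np.ndarray = None
    dif_shift: np.ndarray = None

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        n = self.beta.size
        if n < 2:
            raise ValueError("at least 2 items are required")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("item difficulties must be finite")
        if self.alpha is None:
            self.alpha = np.ones(n)
        if self.gamma is None:
            self.gamma = np.zeros(n)
        if self.dimension is None:
            self.dimension = np.ones(n, dtype=int)
        if self.dif_shift is None:
            self.dif_shift = np.zeros(n)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.dimension = np.asarray(self.dimension, dtype=int)
        self.dif_shift = np.asarray(self.dif_shift, dtype=float)
        if not (self.alpha.size == self.gamma.size == self.dimension.size
                == self.dif_shift.size == n):
            raise ValueError("item parameter vectors must share one length")
        if np.any(self.alpha <= 0):
            raise ValueError("discriminations must be positive")
        if np.any((self.gamma < 0) | (self.gamma >= 1)):
            raise ValueError("pseudo-guessing parameters must lie in [0, 1)")
        if not np.all(np.isin(self.dimension, (1, 2))):
            raise ValueError("dimension labels must be 1 or 2")

    @property
    def n_items(self) -> int:
        return self.beta.size


@dataclass
class ResponseMatrix:
    """An N x n matrix of dichotomous responses with labels."""

    data: np.ndarray
    persons: list = None
    items: list = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("response data must be two-dimensional")
        if not np.all(np.isin(self.data, (0, 1))):
            raise ValueError("responses must be 0 or 1")
        self.data = self.data.astype(np.int8)
        N, n = self.data.shape
        if N < 1 or n < 2:
            raise ValueError("need at least 1 person and 2 items")
        if self.persons is None:
            self.persons = [f"P{j + 1}" for j in range(N)]
        if self.items is None:
            self.items = [f"I{i + 1}" for i in range(n)]
        if len(self.persons) != N or len(self.items) != n:
            raise ValueError("label lengths do not match the data shape")

    @property
    def n_persons(self) -> int:
        return self.data.shape[0]

    @property
    def n_items(self) -> int:
        return self.data.shape[1]

    def raw_scores(self) -> np.ndarray:
        return self.data.sum(axis=1)

    def item_totals(self) -> np.ndarray:
        return self.data.sum(axis=0)


@dataclass
class GeneratingModelSpec:
    """A generating-model family plus its family-specific parameters.

    The study conditions use overwrite_prob in {0.8, 0.9}, trait_corr in
    {0.3, 0.7}, dif_fraction in {0.2, 0.4} with shift -0.8 and class
    proportion 0.40, log_var in {0.09, 0.25}, and guess in {0.1, 0.25};
    any value in the legal range is accepted.
    """

    family: str = "rasch"
    overwrite_prob: float = 0.9
    trait_corr: float = 0.3
    dif_fraction: float = 0.4
    dif_shift: float = -0.8
    class_prop: float = 0.40
    log_var: float = 0.25
    guess: float = 0.25

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if not 0 < self.overwrite_prob <= 1:
            raise ValueError("overwrite_prob must lie in (0, 1]")
        if not -1 <= self.trait_corr <= 1:
            raise ValueError("trait_corr must lie in [-1, 1]")
        if not 0 < self.dif_fraction <= 1:
            raise ValueError("dif_fraction must lie in (0, 1]")
        if not 0 <= self.class_prop <= 1:
            raise ValueError("class_prop must lie in [0, 1]")
        if self.log_var < 0:
            raise ValueError("log_var must be nonnegative")
        if not 0 <= self.guess < 1:
            raise ValueError("guess must lie in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "overwrite_prob": self.overwrite_prob,
            "trait_corr": self.trait_corr,
            "dif_fraction": self.dif_fraction,
            "dif_shift": self.dif_shift,
            "class_prop": self.class_prop,
            "log_var": self.log_var,
            "guess": self.guess,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratingModelSpec":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


# difficulties of the prerequisite / dependent pair in the surface-LD design
SURFACE_LD_BETAS = (-0.626, 0.184)
SURFACE_LD_PREREQ = 0
SURFACE_LD_DEPENDENT = 1


def draw_item_difficulties(n: int, rng: np.random.Generator) -> ItemParameters:
    """Draw n i.i.d. standard normal difficulties (unit slopes, no guessing).

    Within a simulation condition the returned parameters are reused across
    replications; abilities are redrawn per replication.
    """
    if n < 2:
        raise ValueError("at least 2 items are required")
    return ItemParameters(beta=rng.standard_normal(n))


def items_for_spec(spec: GeneratingModelSpec, n: int,
                   rng: np.random.Generator) -> ItemParameters:
    """Draw the per-condition item parameters implied by a generating model.

    Difficulties are standard normal for every family. On top of that:
    surface_ld fixes the special difficulties (-0.626, 0.184) into the first
    two positions; multidim assigns the first half of the items to trait 1
    and the second half to trait 2; mixed_rasch marks the first
    ``dif_fraction`` of items with the DIF shift; twopl draws log-normal
    discriminations once per condition; guessing sets the constant lower
    asymptote.
    """
    items = draw_item_difficulties(n, rng)
    if spec.family == "surface_ld":
        beta = items.beta.copy()
        beta[SURFACE_LD_PREREQ] = SURFACE_LD_BETAS[0]
        beta[SURFACE_LD_DEPENDENT] = SURFACE_LD_BETAS[1]
        items = replace(items, beta=beta)
    elif spec.family == "multidim":
        if n % 2:
            raise ValueError("two-dimensional generation requires an even number of items")
        dimension = np.where(np.arange(n) < n // 2, 1, 2)
        items = replace(items, dimension=dimension)
    elif spec.family == "mixed_rasch":
        n_dif = int(round(spec.dif_fraction * n))
        dif = np.zeros(n)
        dif[:n_dif] = spec.dif_shift
        items = replace(items, dif_shift=dif)
    elif spec.family == "twopl":
        alpha = rng.lognormal(mean=0.0, sigma=np.sqrt(spec.log_var), size=n)
        items = replace(items, alpha=alpha)
    elif spec.family == "guessing":
        items = replace(items, gamma=np.full(n, spec.guess))
    return items


def response_probabilities(spec: GeneratingModelSpec, items: ItemParameters,
                           theta: np.ndarray,
                           class_member: np.ndarray | None = None) -> np.ndarray:
    """Positive-response probability matrix for given abilities.

    theta is (N,) for unidimensional families and (N, 2) for multidim;
    class_member is the 0/1 latent-class indicator for mixed_rasch.
    """
    theta = np.asarray(theta, dtype=float)
    if spec.family == "multidim":
        if theta.ndim != 2 or theta.shape[1] != 2:
            raise ValueError("multidim abilities must have shape (N, 2)")
        theta_eff = theta[:, items.dimension - 1]
    else:
        if theta.ndim != 1:
            raise ValueError("unidimensional abilities must have shape (N,)")
        theta_eff = theta[:, None]
    beta = items.beta[None, :]
    if spec.family == "mixed_rasch":
        if class_member is None:
            raise ValueError("mixed_rasch requires a latent-class indicator")
        beta = beta + np.asarray(class_member)[:, None] * items.dif_shift[None, :]
    logits = items.alpha[None, :] * (theta_eff - beta)
    p = expit(logits)
    if np.any(items.gamma > 0):
        p = items.gamma[None, :] + (1.0 - items.gamma[None, :]) * p
    return p


def generate(spec: GeneratingModelSpec, N: int, items: ItemParameters,
             rng: np.random.Generator) -> ResponseMatrix:
    """Generate an N x n response matrix under the spec's family.

    Abilities (and the latent class for mixed_rasch) are redrawn on every
    call; item parameters are taken as given so they stay fixed across
    replications within a condition. The surface_ld family is a
    post-processing step, not an item response function — use
    :func:`apply_surface_ld` on Rasch data (or :func:`simulate_matrix`).
    """
    if N < 1:
        raise ValueError("N must be positive")
    if spec.family == "surface_ld":
        raise ValueError(
            "surface_ld is applied by apply_surface_ld on Rasch data, not by generate"
        )
    n = items.n_items
    if spec.family == "multidim":
        if n % 2:
            raise ValueError("two-dimensional generation requires an even number of items")
        z = rng.standard_normal((N, 2))
        r = spec.trait_corr
        theta = np.column_stack([z[:, 0], r * z[:, 0] + np.sqrt(1.0 - r * r) * z[:, 1]])
    else:
        theta = rng.standard_normal(N)
    class_member = None
    if spec.family == "mixed_rasch":
        class_member = (rng.random(N) < spec.class_prop).astype(int)
    p = response_probabilities(spec, items, theta, class_member)
    data = (rng.random((N, n)) < p).astype(np.int8)
    return ResponseMatrix(data=data)


def apply_surface_ld(X: ResponseMatrix, prereq_item: int, dependent_item: int,
                     overwrite_prob: float, rng: np.random.Generator) -> ResponseMatrix:
    """Impose a prerequisite relation between two items on Rasch data.

    Among persons solving the dependent item but not the prerequisite, each
    independently has the prerequisite overwritten to positive with
    probability ``overwrite_prob``. No entry is ever decreased and no other
    cell is touched.
    """
    if prereq_item == dependent_item:
        raise ValueError("prerequisite and dependent item must differ")
    if not 0 < overwrite_prob <= 1:
        raise ValueError("overwrite_prob must lie in (0, 1]")
    data = X.data.copy()
    pattern = (data[:, dependent_item] == 1) & (data[:, prereq_item] == 0)
    idx = np.flatnonzero(pattern)
    hit = idx[rng.random(idx.size) < overwrite_prob]
    data[hit, prereq_item] = 1
    return ResponseMatrix(data=data, persons=list(X.persons), items=list(X.items))


def simulate_matrix(spec: GeneratingModelSpec, N: int, items: ItemParameters,
                    rng: np.random.Generator) -> ResponseMatrix:
    """Generate one dataset, including the surface-LD post-processing step."""
    if spec.family == "surface_ld":
        base = generate(GeneratingModelSpec(family="rasch"), N, items, rng)
        return apply_surface_ld(base, SURFACE_LD_PREREQ, SURFACE_LD_DEPENDENT,
                                spec.overwrite_prob, rng)
    return generate(spec, N, items, rng)
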