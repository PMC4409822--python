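"""Monotone contour inference over the dose-combination grid.

A *contour* splits the ``I x J`` lattice into combinations with DLT risk
above the target level ``theta`` and those at or below it.  Under the
monotonicity assumption the above-set must be an up-set (closed under
increasing either dose index), so it is fully described by a nonincreasing
height vector ``h``: ``h[i]`` counts the below-contour cells in drug-A
column ``i``, i.e. cell ``(i, j)`` is above exactly when ``j >= h[i]``.
There are ``C(I + J, I)`` such contours.

The posterior over contours is a product of independent beta tail
probabilities: with ``p_ij = P(pi_ij <= theta | data)``, contour ``C``
scores ``prod_ij [ p_ij if C below at (i,j) else 1 - p_ij ]``, normalized
over the monotone set only.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb

import numpy as np
from scipy.special import logsumexp

from .priors import BetaGrid

__all__ = [
    "TrialData",
    "Contour",
    "ContourDistribution",
    "update_posterior",
    "tail_probability",
    "enumerate_contours",
    "contour_log_probability",
    "contour_posterior",
    "modal_contour",
    "above_mtc_probability",
    "estimate_surface",
]

DEFAULT_CONTOUR_CAP = 10**7


@dataclass
class TrialData:
    """Accumulated patient/DLT counts per dose plus the cohort dosing history.

    ``history`` holds ``(cohort_index, (i, j), n_patients, n_dlts)`` tuples
    in dosing order; the count grids are its marginal totals.
    """

    n: np.ndarray
    x: np.ndarray
    history: list[tuple[int, tuple[int, int], int, int]]

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=int)
        self.x = np.asarray(self.x, dtype=int)
        if self.n.shape != self.x.shape:
            raise ValueError("n and x grids must share a shape")
        if np.any(self.x < 0) or np.any(self.n < 0) or np.any(self.x > self.n):
            raise ValueError("need 0 <= x_ij <= n_ij")

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "TrialData":
        return cls(n=np.zeros(shape, dtype=int), x=np.zeros(shape, dtype=int), history=[])

    @property
    def shape(self) -> tuple[int, int]:
        return self.n.shape

    @property
    def n_cohorts_dosed(self) -> int:
        return len(self.history)

    def doses_given(self) -> set[tuple[int, int]]:
        return {dose for _, dose, _, _ in self.history}

    def add_cohort(self, dose: tuple[int, int], n_patients: int, n_dlts: int) -> None:
        if not (0 <= n_dlts <= n_patients):
            raise ValueError("need 0 <= DLTs <= patients")
        self.n[dose] += n_patients
        self.x[dose] += n_dlts
        self.history.append((len(self.history) + 1, dose, n_patients, n_dlts))

    def copy(self) -> "TrialData":
        return TrialData(n=self.n.copy(), x=self.x.copy(), history=list(self.history))


class Contour:
    """One monotone contour, encoded by its height vector.

    ``heights[i]`` = number of below-contour cells in drug-A column ``i``;
    cell ``(i, j)`` is above iff ``j >= heights[i]``.  The up-set property is
    equivalent to ``heights`` being nonincreasing.
    """

    __slots__ = ("heights", "n_cols")

    def __init__(self, heights: np.ndarray | list[int], n_cols: int):
        h = np.asarray(heights, dtype=int)
        if h.ndim != 1:
            raise ValueError("heights must be a vector")
        if np.any(h < 0) or np.any(h > n_cols):
            raise ValueError(f"heights must lie in [0, {n_cols}]")
        if np.any(np.diff(h) > 0):
            raise ValueError("heights must be nonincreasing (up-set property)")
        self.heights = h
        self.n_cols = int(n_cols)

    @classmethod
    def from_matrix(cls, above: np.ndarray) -> "Contour":
        above = np.asarray(above, dtype=bool)
        I, J = above.shape
        # validate up-set before trusting column counts
        if np.any(above[:-1, :] & ~above[1:, :]) or np.any(above[:, :-1] & ~above[:, 1:]):
            raise ValueError("matrix is not an up-set")
        return cls(heights=J - above.sum(axis=1), n_cols=J)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.heights), self.n_cols)

    @property
    def above(self) -> np.ndarray:
        """Binary matrix, 1 = DLT risk above theta."""
        return (np.arange(self.n_cols)[None, :] >= self.heights[:, None]).astype(int)

    def is_above(self, dose: tuple[int, int]) -> bool:
        return dose[1] >= self.heights[dose[0]]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Contour)
            and self.n_cols == other.n_cols
            and np.array_equal(self.heights, other.heights)
        )

    def __hash__(self) -> int:
        return hash((self.n_cols, tuple(self.heights)))

    def __repr__(self) -> str:
        return f"Contour(heights={self.heights.tolist()}, n_cols={self.n_cols})"


@lru_cache(maxsize=16)
def _contour_stack(I: int, J: int) -> tuple[np.ndarray, np.ndarray]:
    """All monotone contours for an ``I x J`` grid.

    Returns ``(heights, above)`` where ``heights`` is ``(S, I)`` int
    (nonincreasing rows, lexicographic order) and ``above`` is the matching
    ``(S, I * J)`` float 0/1 stack used for vectorized scoring.
    """
    rows: list[list[int]] = []

    def rec(prefix: list[int], cap: int) -> None:
        if len(prefix) == I:
            rows.append(list(prefix))
            return
        for h in range(cap, -1, -1):
            prefix.append(h)
            rec(prefix, h)
            prefix.pop()

    rec([], J)
    heights = np.array(rows, dtype=int)
    above = (np.arange(J)[None, None, :] >= heights[:, :, None]).reshape(len(rows), I * J)
    return heights, above.astype(float)


def update_posterior(prior: BetaGrid, data: TrialData) -> BetaGrid:
    """Conjugate update: ``a += x`` and ``b += n - x`` element-wise."""
    if prior.shape != data.shape:
        raise ValueError("prior and data grids must share a shape")
    return BetaGrid(a=prior.a + data.x, b=prior.b + (data.n - data.x))


def tail_probability(post: BetaGrid, theta: float) -> np.ndarray:
    """``p_ij = F(theta; a_ij, b_ij)``, the per-dose below-target probability."""
    if not 0 < theta < 1:
        raise ValueError("theta must be in (0, 1)")
    return post.tail(theta)


def enumerate_contours(I: int, J: int, cap: int = DEFAULT_CONTOUR_CAP) -> list[Contour]:
    """All ``C(I + J, I)`` monotone contours, in stable lexicographic order."""
    if I < 1 or J < 1:
        raise ValueError("grid dimensions must be >= 1")
    count = comb(I + J, I)
    if count > cap:
        raise ValueError(f"contour count {count} for a {I}x{J} grid exceeds cap {cap}")
    heights, _ = _contour_stack(I, J)
    return [Contour(h, J) for h in heights]


def contour_log_probability(p: np.ndarray, contour: Contour) -> float:
    """Log unnormalized posterior probability of one contour.

    ``sum_ij log(p_ij)`` over below-contour cells plus ``sum_ij log(1 - p_ij)``
    over above cells; ``-inf`` when any factor is exactly zero.
    """
    p = np.asarray(p, dtype=float)
    above = contour.above.astype(bool)
    with np.errstate(divide="ignore"):
        terms = np.where(above, np.log1p(-p), np.log(p))
    return float(terms.sum())


@dataclass(frozen=True)
class ContourDistribution:
    """Posterior over the monotone contour set.

    Contour objects are materialized lazily: simulations touch only the
    modal contour, so building all ``C(I+J, I)`` wrappers per cohort would
    dominate the runtime.
    """

    heights_stack: np.ndarray  # (S, I) int
    log_weights: np.ndarray  # unnormalized
    probs: np.ndarray  # normalized over the monotone set
    _above_stack: np.ndarray  # (S, I*J) float, cached for q computation
    shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.heights_stack)

    def contour(self, k: int) -> Contour:
        return Contour(self.heights_stack[k], self.shape[1])

    @property
    def contours(self) -> list[Contour]:
        return [self.contour(k) for k in range(len(self))]


def contour_posterior(p: np.ndarray, cap: int = DEFAULT_CONTOUR_CAP) -> ContourDistribution:
    """Score every monotone contour against a tail-probability grid.

    Weights are accumulated in log space (up to ``I * J`` factors, each
    possibly tiny) and normalized over the monotone set only.
    """
    p = np.asarray(p, dtype=float)
    I, J = p.shape
    count = comb(I + J, I)
    if count > cap:
        raise ValueError(f"contour count {count} exceeds cap {cap}")
    heights, above = _contour_stack(I, J)
    with np.errstate(divide="ignore"):
        logp = np.log(p.ravel())
        log1mp = np.log1p(-p.ravel())
    if np.all(np.isfinite(logp)) and np.all(np.isfinite(log1mp)):
        log_w = logp.sum() + above @ (log1mp - logp)
    else:
        # some p_ij is exactly 0 or 1: per-contour sums avoid inf - inf
        log_w = np.where(above > 0.5, log1mp[None, :], logp[None, :]).sum(axis=1)
    if np.all(np.isneginf(log_w)):
        raise ValueError("degenerate contour posterior: all contours have zero probability")
    probs = np.exp(log_w - logsumexp(log_w))
    probs /= probs.sum()
    return ContourDistribution(
        heights_stack=heights, log_weights=log_w, probs=probs, _above_stack=above, shape=(I, J)
    )


def modal_contour(
    dist: ContourDistribution, rng: np.random.Generator | None = None, rel_tol: float = 1e-12
) -> Contour:
    """Contour with maximal posterior weight; ties broken uniformly at random."""
    log_w = dist.log_weights
    best = log_w.max()
    ties = np.flatnonzero(log_w >= best - rel_tol * max(1.0, abs(best)))
    if len(ties) == 1:
        return dist.contour(int(ties[0]))
    if rng is None:
        rng = np.random.default_rng()
    return dist.contour(int(rng.choice(ties)))


def above_mtc_probability(dist: ContourDistribution) -> np.ndarray:
    """``q_ij = P(dose (i, j) above the contour)``, averaged over contours."""
    q = dist.probs @ dist._above_stack
    return q.reshape(dist.shape)


def estimate_surface(
    post: BetaGrid, theta_list: list[float], rng: np.random.Generator | None = None
) -> list[tuple[float, Contour]]:
    """Modal contour per target level; above-sets forced to nest as theta grows.

    Violations of nesting (rare, from modal ties or non-monotone posteriors)
    are resolved toward the higher-theta contour: sweeping from the largest
    theta down, each lower-theta above-set is enlarged to contain the one
    above it.
    """
    thetas = list(theta_list)
    if any(not 0 < t < 1 for t in thetas) or any(
        t2 <= t1 for t1, t2 in zip(thetas, thetas[1:])
    ):
        raise ValueError("theta values must be strictly increasing in (0, 1)")
    modal = []
    for t in thetas:
        dist = contour_posterior(tail_probability(post, t))
        modal.append(modal_contour(dist, rng))
    J = post.shape[1]
    heights = [c.heights.copy() for c in modal]
    for k in range(len(thetas) - 2, -1, -1):
        heights[k] = np.minimum(heights[k], heights[k + 1])
    return [(t, Contour(h, J)) for t, h in zip(thetas, heights)]
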