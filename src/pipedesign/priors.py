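"""Beta prior calibration from elicited median DLT probabilities.

Each dose combination ``(i, j)`` on an ``I x J`` grid (``i`` indexes drug A,
``j`` indexes drug B, toxicity nondecreasing in both) carries an independent
``Beta(a_ij, b_ij)`` prior on its DLT probability.  The trialist supplies a
grid of prior *median* DLT probabilities (possibly with gaps) plus a prior
*strength* grid ``s_ij = a_ij + b_ij`` (the effective number of pseudo
patients).  Calibration solves ``F(med; a, s - a) = 0.5`` for ``a`` at every
cell, where ``F`` is the beta CDF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import betainc
from scipy.stats import beta as beta_dist

__all__ = [
    "PriorSpec",
    "BetaGrid",
    "ElicitationError",
    "calibrate_beta",
    "complete_median_grid",
    "calibrate_grid",
]

_A_EDGE = 1e-10  # relative bracket inset for the root search on a in (0, s)


class ElicitationError(ValueError):
    """Raised when an elicited prior specification is internally inconsistent."""


@dataclass(frozen=True)
class BetaGrid:
    """Grid of beta hyperparameters, one ``Beta(a_ij, b_ij)`` per dose.

    Represents either a prior or a posterior over the per-dose DLT
    probabilities.  Both arrays must be strictly positive and share a shape.
    """

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.shape != b.shape:
            raise ValueError(f"shape mismatch: a {a.shape} vs b {b.shape}")
        if not (np.all(a > 0) and np.all(b > 0)):
            raise ValueError("beta hyperparameters must be strictly positive")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def shape(self) -> tuple[int, int]:
        return self.a.shape

    @property
    def strength(self) -> np.ndarray:
        """Effective sample size ``a_ij + b_ij`` per dose."""
        return self.a + self.b

    def median(self) -> np.ndarray:
        return beta_dist.median(self.a, self.b)

    def tail(self, theta: float) -> np.ndarray:
        """``P(pi_ij <= theta)`` per dose (regularized incomplete beta)."""
        return betainc(self.a, self.b, theta)


@dataclass
class PriorSpec:
    """Elicited prior: median DLT grid (NaN = unspecified), strengths, target.

    ``strength`` may be a scalar (shared by every dose) or a full grid.
    ``mtc_doses`` optionally names 0-based dose combinations the trialist
    believes sit closest to the target contour; their median is pinned to
    ``theta`` before interpolation.
    """

    medians: np.ndarray
    strength: np.ndarray | float
    theta: float
    mtc_doses: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        med = np.array(self.medians, dtype=float)
        if med.ndim != 2:
            raise ValueError("median grid must be 2-dimensional")
        spec = ~np.isnan(med)
        if np.any((med[spec] <= 0) | (med[spec] >= 1)):
            raise ElicitationError("specified medians must lie strictly in (0, 1)")
        s = np.broadcast_to(np.asarray(self.strength, dtype=float), med.shape).copy()
        if np.any(s <= 0):
            raise ElicitationError("prior strengths must be positive")
        if not 0 < self.theta < 1:
            raise ValueError("theta must lie in (0, 1)")
        for i, j in self.mtc_doses:
            med[i, j] = self.theta
        self.medians = med
        self.strength = s

    @property
    def shape(self) -> tuple[int, int]:
        return self.medians.shape

    @property
    def is_complete(self) -> bool:
        return not np.any(np.isnan(self.medians))


def calibrate_beta(med: float, s: float, tol: float = 1e-10) -> tuple[float, float]:
    """Solve ``F(med; a, s - a) = 0.5`` for ``a``; return ``(a, s - a)``.

    ``g(a) = F(med; a, s - a) - 0.5`` is continuous and strictly decreasing
    in ``a`` (mass moves from 0 toward 1), so a bracketed root search on
    ``(eps, s - eps)`` is robust even at tiny strengths.

    Parameters
    ----------
    med : prior median DLT probability, in (0, 1).
    s : prior strength (effective sample size), > 0.

    Returns
    -------
    (a, b) with ``a + b == s`` and the beta median equal to ``med``.
    """
    if not 0 < med < 1:
        raise ValueError(f"median must be in (0, 1), got {med}")
    if not s > 0:
        raise ValueError(f"strength must be positive, got {s}")
    lo, hi = _A_EDGE * s, (1 - _A_EDGE) * s
    a = brentq(lambda a_: betainc(a_, s - a_, med) - 0.5, lo, hi, xtol=tol * min(1.0, s))
    return float(a), float(s - a)


def _interpolate_missing(med: np.ndarray) -> np.ndarray:
    """Fill NaNs by interpolating specified cells on the log-odds scale.

    Linear interpolation over the dose-index lattice anchored at the
    specified cells (nearest-anchor extension outside their convex hull),
    followed by an axis-wise monotone sweep over the *filled* cells only.
    """
    from scipy.interpolate import griddata
    from scipy.spatial import QhullError

    out = med.copy()
    spec = ~np.isnan(med)
    pts = np.argwhere(spec).astype(float)
    logit = np.log(med[spec] / (1 - med[spec]))
    gi, gj = np.mgrid[0 : med.shape[0], 0 : med.shape[1]]
    grid_pts = np.column_stack([gi.ravel(), gj.ravel()]).astype(float)
    vals = np.full(len(grid_pts), np.nan)
    if len(pts) >= 3:
        try:
            vals = griddata(pts, logit, grid_pts, method="linear")
        except QhullError:
            # anchors collinear (e.g. a diagonal): interpolate along their axis
            centre = pts.mean(axis=0)
            _, _, vt = np.linalg.svd(pts - centre, full_matrices=False)
            d = vt[0] if vt[0].sum() >= 0 else -vt[0]
            t_anchor = (pts - centre) @ d
            order = np.argsort(t_anchor)
            vals = np.interp((grid_pts - centre) @ d, t_anchor[order], logit[order])
    near = griddata(pts, logit, grid_pts, method="nearest")
    vals = np.where(np.isnan(vals), near, vals)
    filled = 1 / (1 + np.exp(-vals.reshape(med.shape)))
    out[~spec] = filled[~spec]
    # monotone repair restricted to interpolated cells: each cell must be at
    # least the max of its lower neighbours
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            if spec[i, j]:
                continue
            floor = 0.0
            if i > 0:
                floor = max(floor, out[i - 1, j])
            if j > 0:
                floor = max(floor, out[i, j - 1])
            out[i, j] = max(out[i, j], floor)
    return out


def _check_monotone(grid: np.ndarray) -> bool:
    return bool(
        np.all(np.diff(grid, axis=0) >= -1e-12) and np.all(np.diff(grid, axis=1) >= -1e-12)
    )


def complete_median_grid(spec: PriorSpec) -> PriorSpec:
    """Return a copy of ``spec`` with missing medians filled by interpolation.

    Specified entries are left untouched.  The completed grid must be
    monotone nondecreasing in both dose indices; if the specified anchors
    already contradict monotonicity an :class:`ElicitationError` is raised.
    """
    med = spec.medians
    known = ~np.isnan(med)
    if not known.any():
        raise ElicitationError("at least one median must be specified")
    # anchor consistency: any specified pair ordered componentwise must be
    # ordered in value
    idx = np.argwhere(known)
    for i1, j1 in idx:
        for i2, j2 in idx:
            if i1 <= i2 and j1 <= j2 and med[i1, j1] > med[i2, j2] + 1e-12:
                raise ElicitationError(
                    f"specified medians violate monotonicity: "
                    f"({i1},{j1})={med[i1, j1]} > ({i2},{j2})={med[i2, j2]}"
                )
    if spec.is_complete:
        filled = med.copy()
    else:
        filled = _interpolate_missing(med)
    if not _check_monotone(filled):
        raise ElicitationError("interpolation could not produce a monotone grid")
    return PriorSpec(medians=filled, strength=spec.strength, theta=spec.theta)


def calibrate_grid(spec: PriorSpec) -> BetaGrid:
    """Element-wise :func:`calibrate_beta` over a complete prior spec."""
    if not spec.is_complete:
        spec = complete_median_grid(spec)
    I, J = spec.shape
    a = np.empty((I, J))
    b = np.empty((I, J))
    for i in range(I):
        for j in range(J):
            try:
                a[i, j], b[i, j] = calibrate_beta(spec.medians[i, j], spec.strength[i, j])
            except ValueError as err:
                raise ValueError(f"calibration failed at dose ({i}, {j}): {err}") from err
    return BetaGrid(a=a, b=b)
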