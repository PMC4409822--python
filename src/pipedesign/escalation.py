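"""Dose-escalation policy: admissible sets, constraints, selection, RPII.

Doses are 0-based ``(i, j)`` index pairs, ``i`` for drug A and ``j`` for
drug B.  "Closest" doses are the maximal elements (componentwise order) of
the below-contour set together with the minimal elements of the above set;
"adjacent" doses are every cell with at least one edge on the contour's
staircase curve.  Dose-skipping, safety and coherence filters are set
intersections applied in a fixed order, with a largest-dose fallback when
the strategy set is vetoed by the constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contours import Contour, TrialData
from .priors import BetaGrid

__all__ = [
    "DesignOptions",
    "AdmissibleSet",
    "partition",
    "closest_doses",
    "adjacent_doses",
    "apply_neighbourhood_constraint",
    "apply_non_neighbourhood_constraint",
    "apply_safety_constraint",
    "apply_coherence",
    "fallback_largest",
    "select_dose",
    "recommend_phase2",
]

Dose = tuple[int, int]

STRATEGIES = ("closest", "adjacent")
SELECTIONS = ("min_sample_size", "weighted_randomisation")
CONSTRAINTS = ("neighbourhood", "non_neighbourhood", "none")


@dataclass
class DesignOptions:
    """All switches needed to run one PIPE trial."""

    theta: float
    epsilon: float = 0.8
    cohort_size: int = 2
    n_cohorts: int = 20
    strategy: str = "closest"
    selection: str = "min_sample_size"
    constraint: str = "neighbourhood"
    coherence: bool = False
    start_dose: Dose = (0, 0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.theta < 1:
            raise ValueError("theta must be in (0, 1)")
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must be in (0, 1]")
        if self.cohort_size < 1 or self.n_cohorts < 1:
            raise ValueError("cohort size and count must be positive")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.selection not in SELECTIONS:
            raise ValueError(f"selection must be one of {SELECTIONS}")
        if self.constraint not in CONSTRAINTS:
            raise ValueError(f"constraint must be one of {CONSTRAINTS}")


@dataclass
class AdmissibleSet:
    """Candidate doses for the next cohort, with per-dose provenance tags."""

    doses: set[Dose]
    provenance: dict[Dose, str] = field(default_factory=dict)

    def __bool__(self) -> bool:
        return bool(self.doses)

    def __len__(self) -> int:
        return len(self.doses)

    def __iter__(self):
        return iter(self.doses)

    def restricted(self, keep: set[Dose]) -> "AdmissibleSet":
        doses = self.doses & keep
        return AdmissibleSet(doses, {d: self.provenance.get(d, "") for d in doses})


def partition(contour: Contour) -> tuple[set[Dose], set[Dose]]:
    """Split the grid into (below-or-at, above) dose sets."""
    I, J = contour.shape
    below = {(i, j) for i in range(I) for j in range(J) if j < contour.heights[i]}
    above = {(i, j) for i in range(I) for j in range(J) if j >= contour.heights[i]}
    return below, above


def _maximal(doses: set[Dose]) -> set[Dose]:
    return {
        d
        for d in doses
        if not any(e != d and e[0] >= d[0] and e[1] >= d[1] for e in doses)
    }


def _minimal(doses: set[Dose]) -> set[Dose]:
    return {
        d
        for d in doses
        if not any(e != d and e[0] <= d[0] and e[1] <= d[1] for e in doses)
    }


def closest_doses(contour: Contour, within: set[Dose] | None = None) -> AdmissibleSet:
    """Maximal below-contour doses plus minimal above-contour doses.

    Under monotonicity these are the combinations nearest the contour in
    toxicity: every other below dose is dominated by a maximal-below one.
    When ``within`` is given (a dose-skipping box, possibly already
    safety-filtered), the maximal/minimal elements are taken *inside* that
    set — the closest doses identifiable given the current constraint —
    rather than globally and then intersected.
    """
    if within is None:
        h = contour.heights
        I, J = contour.shape
        doses: set[Dose] = set()
        prov: dict[Dose, str] = {}
        for i in range(I):
            nxt = h[i + 1] if i + 1 < I else 0
            if h[i] > nxt:  # strict drop: (i, h[i]-1) is maximal below
                doses.add((i, h[i] - 1))
                prov[(i, h[i] - 1)] = "closest_below"
            prev = h[i - 1] if i > 0 else J + 1
            if h[i] < J and h[i] < prev:  # (i, h[i]) is minimal above
                doses.add((i, h[i]))
                prov[(i, h[i])] = "closest_above"
        return AdmissibleSet(doses, prov)
    below = {d for d in within if not contour.is_above(d)}
    above = {d for d in within if contour.is_above(d)}
    prov = {d: "closest_below" for d in _maximal(below)}
    prov.update({d: "closest_above" for d in _minimal(above)})
    return AdmissibleSet(set(prov), prov)


def adjacent_doses(contour: Contour, within: set[Dose] | None = None) -> AdmissibleSet:
    """Every cell with an edge on the contour's staircase curve.

    The curve is the step function at height ``h[i]`` across column ``i``
    (drawn over the full grid width) with vertical jumps at drops; a
    superset of the closest doses.  ``within`` restricts to a constraint
    set (adjacency itself is a property of the curve, so this is a plain
    intersection).
    """
    h = contour.heights
    I, J = contour.shape
    closest = closest_doses(contour)
    doses: set[Dose] = set()
    for i in range(I):
        if h[i] >= 1:  # top edge of (i, h[i]-1) on the horizontal segment
            doses.add((i, h[i] - 1))
        if h[i] < J:  # bottom edge of (i, h[i])
            doses.add((i, h[i]))
        if i + 1 < I and h[i] > h[i + 1]:  # vertical jump between columns i, i+1
            for j in range(h[i + 1], h[i]):
                doses.add((i, j))  # right edge on the jump
                doses.add((i + 1, j))  # left edge on the jump
    if within is not None:
        doses &= within
    prov = {d: closest.provenance.get(d, "adjacent_only") for d in doses}
    return AdmissibleSet(doses, prov)


def apply_neighbourhood_constraint(doses: set[Dose], current: Dose) -> set[Dose]:
    """Keep doses within one level of the current dose in both drugs."""
    ci, cj = current
    return {d for d in doses if abs(d[0] - ci) <= 1 and abs(d[1] - cj) <= 1}


def apply_non_neighbourhood_constraint(
    doses: set[Dose], history: set[Dose] | list[Dose]
) -> set[Dose]:
    """Keep doses at most one level above *some* previously administered dose."""
    hist = set(history)
    if not hist:
        raise ValueError("non-neighbourhood constraint needs a nonempty history")
    return {
        d for d in doses if any(d[0] <= hi + 1 and d[1] <= hj + 1 for hi, hj in hist)
    }


def apply_safety_constraint(
    doses: set[Dose], q: np.ndarray, epsilon: float
) -> set[Dose]:
    """Drop doses whose above-contour probability reaches ``epsilon``.

    An empty result is the trial-termination signal, not an error.
    """
    return {d for d in doses if q[d] < epsilon}


def apply_coherence(
    adm: AdmissibleSet, contour: Contour, current: Dose, last_dlts: int | None = None
) -> AdmissibleSet:
    """Keep only doses on the far side of the contour from the current dose.

    The contour has already adapted to the last outcome, so restricting to
    the opposite side yields escalation after no DLTs and de-escalation
    after DLTs.  ``last_dlts`` is accepted for audit but not needed.
    """
    if contour.is_above(current):
        keep = {d for d in adm.doses if not contour.is_above(d)}
    else:
        keep = {d for d in adm.doses if contour.is_above(d)}
    return adm.restricted(keep)


def fallback_largest(constrained: set[Dose], contour: Contour) -> AdmissibleSet:
    """Largest-dose fallback when the strategy set is vetoed by constraints.

    If the constrained set still holds below-contour doses, take their
    maximal elements (diagonal escalation toward the contour); otherwise the
    whole box sits above the contour and we take its minimal elements
    (forced de-escalation).
    """
    if not constrained:
        raise ValueError("fallback requires a nonempty constrained set")
    below = {d for d in constrained if not contour.is_above(d)}
    chosen = _maximal(below) if below else _minimal(constrained)
    return AdmissibleSet(chosen, {d: "largest_fallback" for d in chosen})


def select_dose(
    adm: AdmissibleSet,
    prior: BetaGrid,
    data: TrialData,
    rule: str,
    rng: np.random.Generator,
) -> Dose:
    """Pick the next dose by (prior + trial) sample size ``a + b + n``.

    ``min_sample_size``: argmin, ties broken uniformly at random.
    ``weighted_randomisation``: draw with probability proportional to the
    inverse sample size.
    """
    if not adm:
        raise ValueError("cannot select from an empty admissible set")
    doses = sorted(adm.doses)
    totals = np.array([prior.strength[d] + data.n[d] for d in doses])
    if rule == "min_sample_size":
        ties = np.flatnonzero(totals <= totals.min() * (1 + 1e-12))
        return doses[int(rng.choice(ties))]
    if rule == "weighted_randomisation":
        w = 1.0 / totals
        return doses[int(rng.choice(len(doses), p=w / w.sum()))]
    raise ValueError(f"unknown selection rule: {rule}")


def recommend_phase2(final_contour: Contour, data: TrialData) -> set[Dose]:
    """Recommended phase II doses: combinations closest from below to the
    final contour that were experimented on during the trial.

    The closest-below cells of the contour (maximal elements of its below
    set) intersected with the experimented doses.  May be empty — e.g. a
    trial stopped early for safety, or one whose experimentation never
    reached the final contour — in which case no dose is recommended.
    Always an antichain.
    """
    closest_below = {
        d
        for d, tag in closest_doses(final_contour).provenance.items()
        if tag == "closest_below"
    }
    return {d for d in closest_below if data.n[d] > 0}
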