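"""Single-trial mechanics and Monte-Carlo operating characteristics.

One cohort step: conjugate posterior update, modal contour, admissible set
(strategy -> dose-skipping constraint -> safety -> optional coherence ->
largest-dose fallback), sample-size-based selection, binomial DLT draw.
Trials stop early when no dose inside the current constraint passes the
safety threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contours import (
    Contour,
    TrialData,
    above_mtc_probability,
    contour_posterior,
    modal_contour,
    tail_probability,
    update_posterior,
)
from .escalation import (
    AdmissibleSet,
    DesignOptions,
    adjacent_doses,
    apply_coherence,
    apply_neighbourhood_constraint,
    apply_non_neighbourhood_constraint,
    apply_safety_constraint,
    closest_doses,
    fallback_largest,
    recommend_phase2,
    select_dose,
)
from .priors import BetaGrid
from .scenarios import Scenario

__all__ = [
    "CohortDecision",
    "TrialResult",
    "OperatingCharacteristics",
    "decide_next_dose",
    "simulate_trial",
    "simulate_many",
]

Dose = tuple[int, int]


@dataclass
class CohortDecision:
    """Everything produced while choosing one cohort's dose."""

    dose: Dose | None  # None = terminate for safety
    contour: Contour
    q: np.ndarray
    admissible: AdmissibleSet
    terminated: bool = False


@dataclass
class TrialResult:
    data: TrialData
    rpii: set[Dose]
    stopped_early: bool
    final_contour: Contour

    @property
    def n_treated(self) -> int:
        return int(self.data.n.sum())

    @property
    def n_dlts(self) -> int:
        return int(self.data.x.sum())


def _all_cells(shape: tuple[int, int]) -> set[Dose]:
    return {(i, j) for i in range(shape[0]) for j in range(shape[1])}


def decide_next_dose(
    prior: BetaGrid,
    data: TrialData,
    options: DesignOptions,
    rng: np.random.Generator,
) -> CohortDecision:
    """Choose the next cohort's dose from the current trial state.

    The first cohort is dosed at ``options.start_dose`` (subject only to the
    safety threshold).  Later cohorts intersect the strategy set with the
    dose-skipping box and the safe set, optionally apply coherence, and fall
    back to the largest safe in-box dose when that intersection is empty.
    An empty safe in-box set terminates the trial.
    """
    post = update_posterior(prior, data)
    p = tail_probability(post, options.theta)
    dist = contour_posterior(p)
    contour = modal_contour(dist, rng)
    q = above_mtc_probability(dist)

    if data.n_cohorts_dosed == 0:
        start = options.start_dose
        if q[start] >= options.epsilon:
            return CohortDecision(None, contour, q, AdmissibleSet(set()), terminated=True)
        adm = AdmissibleSet({start}, {start: "start"})
        return CohortDecision(start, contour, q, adm)

    current = data.history[-1][1]
    if options.constraint == "neighbourhood":
        box = apply_neighbourhood_constraint(_all_cells(data.shape), current)
    elif options.constraint == "non_neighbourhood":
        box = apply_non_neighbourhood_constraint(_all_cells(data.shape), data.doses_given())
    else:
        box = _all_cells(data.shape)

    allowed = apply_safety_constraint(box, q, options.epsilon)
    if not allowed:
        return CohortDecision(None, contour, q, AdmissibleSet(set()), terminated=True)

    if options.strategy == "closest":
        cand = closest_doses(contour, within=allowed)
    else:
        cand = adjacent_doses(contour, within=allowed)
    if options.coherence and cand:
        cand = apply_coherence(cand, contour, current, data.history[-1][3])
    if not cand:
        cand = fallback_largest(allowed, contour)

    dose = select_dose(cand, prior, data, options.selection, rng)
    return CohortDecision(dose, contour, q, cand)


def simulate_trial(
    scenario: Scenario,
    options: DesignOptions,
    prior: BetaGrid,
    rng: np.random.Generator,
) -> TrialResult:
    """Run one complete trial under a known truth grid."""
    if scenario.shape != prior.shape:
        raise ValueError("scenario and prior grids must share a shape")
    data = TrialData.empty(scenario.shape)
    stopped = False
    for _ in range(options.n_cohorts):
        decision = decide_next_dose(prior, data, options, rng)
        if decision.dose is None:
            stopped = True
            break
        dlts = int(rng.binomial(options.cohort_size, scenario.truth[decision.dose]))
        data.add_cohort(decision.dose, options.cohort_size, dlts)

    post = update_posterior(prior, data)
    dist = contour_posterior(tail_probability(post, options.theta))
    final_contour = modal_contour(dist, rng)
    rpii = set() if stopped else recommend_phase2(final_contour, data)
    return TrialResult(data=data, rpii=rpii, stopped_early=stopped, final_contour=final_contour)


@dataclass
class OperatingCharacteristics:
    """Aggregated experimentation/recommendation summaries by toxicity band.

    ``experimentation_pct`` uses treated patients as the denominator;
    ``untreated_pct`` reports the share of *planned* patients never enrolled
    (nonzero only when trials stop early).  Recommendation percentages are
    per selected dose, pooled across trials; ``none_pct`` is the share of
    trials recommending nothing.  Rounding happens only at render time.
    """

    band_labels: list[str]
    experimentation_pct: dict[str, float]
    recommendation_pct: dict[str, float]
    untreated_pct: float
    none_pct: float
    mean_n_recommended: float
    n_trials: int
    total_treated: int
    total_planned: int
    experimentation_counts: dict[str, int] = field(default_factory=dict)
    recommendation_counts: dict[str, int] = field(default_factory=dict)

    @property
    def mean_cohorts_dosed(self) -> float:
        return self.total_treated / self.n_trials  # patients; divide by cohort size upstream


def aggregate_results(
    results: list[TrialResult], scenario: Scenario, options: DesignOptions
) -> OperatingCharacteristics:
    labels = scenario.band_labels
    exp_counts = dict.fromkeys(labels, 0)
    rec_counts = dict.fromkeys(labels, 0)
    total_rec = 0
    n_none = 0
    for res in results:
        nz = np.argwhere(res.data.n > 0)
        for i, j in nz:
            exp_counts[scenario.band_of((int(i), int(j)))] += int(res.data.n[i, j])
        if res.rpii:
            for dose in res.rpii:
                rec_counts[scenario.band_of(dose)] += 1
                total_rec += 1
        else:
            n_none += 1
    n_trials = len(results)
    total_treated = sum(r.n_treated for r in results)
    total_planned = n_trials * options.cohort_size * options.n_cohorts
    exp_pct = {
        lab: 100.0 * c / total_treated if total_treated else 0.0
        for lab, c in exp_counts.items()
    }
    rec_pct = {
        lab: 100.0 * c / total_rec if total_rec else 0.0 for lab, c in rec_counts.items()
    }
    return OperatingCharacteristics(
        band_labels=labels,
        experimentation_pct=exp_pct,
        recommendation_pct=rec_pct,
        untreated_pct=100.0 * (total_planned - total_treated) / total_planned,
        none_pct=100.0 * n_none / n_trials,
        mean_n_recommended=sum(len(r.rpii) for r in results) / n_trials,
        n_trials=n_trials,
        total_treated=total_treated,
        total_planned=total_planned,
        experimentation_counts=exp_counts,
        recommendation_counts=rec_counts,
    )


def simulate_many(
    scenario: Scenario,
    options: DesignOptions,
    prior: BetaGrid,
    n_trials: int,
    seed: int | None = None,
) -> OperatingCharacteristics:
    """Monte-Carlo operating characteristics over independent trials.

    Each trial gets its own RNG substream spawned from ``seed``, so results
    do not depend on execution order.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    if seed is None:
        seed = options.seed
    streams = np.random.SeedSequence(seed).spawn(n_trials)
    results = [
        simulate_trial(scenario, options, prior, np.random.default_rng(s)) for s in streams
    ]
    return aggregate_results(results, scenario, options)
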