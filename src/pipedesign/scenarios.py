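"""True-toxicity scenario grids for operating-characteristics studies.

Named fixtures reproduce the published benchmark grids: four 6x6 scenarios
(target 30%, cohorts of 2) and two 4x4 scenarios (target 20%, single-patient
cohorts).  Grids are stored here in display orientation — rows are drug B
from highest to lowest level, columns drug A ascending — and converted to
the internal ``(i, j) = (drug A, drug B)`` convention on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Scenario",
    "STUDY1_BANDS",
    "make_scenario",
    "band_classify",
    "relative_band_classify",
    "SCENARIO_KINDS",
]

Band = tuple[str, float, float]

# Study-1 true-toxicity bands (percent labels).  All printed truths are
# multiples of 0.005, so edges at x.xx5 make band membership unambiguous and
# match the bold-at-+/-0.025 MTD convention.
STUDY1_BANDS: list[Band] = [
    ("0-14", 0.0, 0.145),
    ("15-24", 0.145, 0.245),
    ("25-34", 0.245, 0.345),
    ("35-45", 0.345, 0.455),
    ("46+", 0.455, 1.0),
]

STUDY2_BAND_LABELS = ["at_theta", "within_10", "over_10"]


def band_classify(value: float, bands: list[Band]) -> str:
    """Label for a true toxicity under half-open bands ``[lo, hi)`` (last closed)."""
    for k, (label, lo, hi) in enumerate(bands):
        last = k == len(bands) - 1
        if lo <= value < hi or (last and value == hi):
            return label
    raise ValueError(f"value {value} falls outside the configured bands")


def relative_band_classify(
    value: float, theta: float, width: float = 0.10, tol: float = 1e-9
) -> str:
    """Distance-to-target label: exactly at theta, within ``width``, or beyond."""
    d = abs(value - theta)
    if d <= tol:
        return "at_theta"
    if d <= width + tol:
        return "within_10"
    return "over_10"


@dataclass
class Scenario:
    """A true DLT-probability grid with its target level and banding scheme."""

    truth: np.ndarray
    theta: float
    name: str = ""
    bands: list[Band] | None = field(default_factory=lambda: list(STUDY1_BANDS))
    # bands=None selects the distance-to-target scheme (at / within 10 / over)

    def __post_init__(self) -> None:
        t = np.asarray(self.truth, dtype=float)
        if np.any(t <= 0) or np.any(t >= 1):
            raise ValueError("true DLT probabilities must lie strictly in (0, 1)")
        if np.any(np.diff(t, axis=0) < -1e-12) or np.any(np.diff(t, axis=1) < -1e-12):
            raise ValueError("true DLT probabilities must be monotone in both doses")
        self.truth = t

    @property
    def shape(self) -> tuple[int, int]:
        return self.truth.shape

    @property
    def band_labels(self) -> list[str]:
        if self.bands is None:
            return list(STUDY2_BAND_LABELS)
        return [label for label, _, _ in self.bands]

    def band_of(self, dose: tuple[int, int]) -> str:
        value = float(self.truth[dose])
        if self.bands is None:
            return relative_band_classify(value, self.theta)
        return band_classify(value, self.bands)


def _from_display(rows_b_desc: list[list[float]]) -> np.ndarray:
    """Display layout (drug B descending rows x drug A columns) -> (A, B) grid."""
    return np.flipud(np.asarray(rows_b_desc, dtype=float)).T.copy()


_TABLE1 = {
    "table1_s1": [  # in agreement with prior
        [0.23, 0.27, 0.30, 0.36, 0.44, 0.49],
        [0.18, 0.21, 0.26, 0.30, 0.39, 0.44],
        [0.11, 0.14, 0.18, 0.23, 0.30, 0.36],
        [0.06, 0.09, 0.14, 0.18, 0.26, 0.30],
        [0.03, 0.05, 0.09, 0.13, 0.21, 0.27],
        [0.02, 0.03, 0.06, 0.10, 0.18, 0.23],
    ],
    "table1_s2": [  # toxic
        [0.23, 0.30, 0.45, 0.50, 0.55, 0.60],
        [0.18, 0.21, 0.30, 0.45, 0.50, 0.55],
        [0.11, 0.14, 0.18, 0.30, 0.45, 0.50],
        [0.06, 0.09, 0.14, 0.18, 0.30, 0.45],
        [0.03, 0.05, 0.09, 0.13, 0.21, 0.30],
        [0.02, 0.03, 0.06, 0.10, 0.18, 0.23],
    ],
    "table1_s3": [  # asymmetric toxic
        [0.30, 0.38, 0.48, 0.58, 0.68, 0.78],
        [0.22, 0.30, 0.40, 0.50, 0.60, 0.70],
        [0.17, 0.25, 0.35, 0.45, 0.50, 0.60],
        [0.12, 0.20, 0.30, 0.40, 0.45, 0.55],
        [0.06, 0.14, 0.24, 0.34, 0.39, 0.49],
        [0.02, 0.10, 0.20, 0.30, 0.35, 0.45],
    ],
    "table1_s4": [  # flat surface
        [0.265, 0.295, 0.325, 0.355, 0.385, 0.415],
        [0.250, 0.280, 0.310, 0.340, 0.370, 0.400],
        [0.235, 0.265, 0.295, 0.325, 0.355, 0.385],
        [0.220, 0.250, 0.280, 0.310, 0.340, 0.370],
        [0.205, 0.235, 0.265, 0.295, 0.325, 0.355],
        [0.190, 0.220, 0.250, 0.280, 0.310, 0.340],
    ],
}

# 4x4 grids printed as percentages, drug B ascending rows in the source; the
# display convention here wants B descending, so rows are reversed.
_TABLE2_B_ASC = {
    "table2_A": [
        [4, 8, 12, 16],
        [10, 14, 18, 22],
        [16, 20, 24, 28],
        [22, 26, 30, 34],
    ],
    "table2_E": [
        [8, 18, 28, 29],
        [9, 19, 29, 30],
        [10, 20, 30, 31],
        [11, 21, 31, 41],
    ],
}

SCENARIO_KINDS = tuple(_TABLE1) + tuple(_TABLE2_B_ASC) + ("random_monotone",)


def make_scenario(
    kind: str,
    params: dict | None = None,
    rng: np.random.Generator | None = None,
) -> Scenario:
    """Build a named benchmark scenario or a random monotone grid.

    ``random_monotone`` draws i.i.d. increments over the lattice and takes
    cumulative sums along both axes (then rescales into ``(lo, hi)``), which
    guarantees monotonicity in both indices.  ``params`` keys: ``shape``,
    ``theta``, ``lo``, ``hi``.
    """
    params = params or {}
    if kind in _TABLE1:
        return Scenario(
            truth=_from_display(_TABLE1[kind]),
            theta=params.get("theta", 0.30),
            name=kind,
            bands=list(STUDY1_BANDS),
        )
    if kind in _TABLE2_B_ASC:
        pct = np.asarray(_TABLE2_B_ASC[kind], dtype=float) / 100.0
        return Scenario(
            truth=pct.T.copy(),  # rows were B ascending already
            theta=params.get("theta", 0.20),
            name=kind,
            bands=None,
        )
    if kind == "random_monotone":
        if rng is None:
            rng = np.random.default_rng()
        I, J = params.get("shape", (4, 4))
        lo, hi = params.get("lo", 0.02), params.get("hi", 0.8)
        inc = rng.exponential(size=(I, J))
        cum = inc.cumsum(axis=0).cumsum(axis=1)
        truth = lo + (hi - lo) * (cum - cum.min()) / (cum.max() - cum.min() + 1e-12)
        truth = np.clip(truth, lo, hi)
        return Scenario(
            truth=truth,
            theta=params.get("theta", 0.30),
            name="random_monotone",
            bands=list(STUDY1_BANDS),
        )
    raise ValueError(f"unknown scenario kind {kind!r}; choose from {SCENARIO_KINDS}")
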