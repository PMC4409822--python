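"""File formats: grid CSV, YAML config, trial-state persistence, OC tables.

Grid files are plain CSV.  Orientation is explicit to prevent silent
transposition: by default rows are drug B levels from *highest to lowest*
(matching the usual display layout) and columns are drug A ascending; a
``row_order`` flag of ``"b_asc"`` flips that.  Missing median entries are
blank cells.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .contours import TrialData
from .escalation import DesignOptions
from .priors import PriorSpec
from .simulate import OperatingCharacteristics

__all__ = [
    "read_grid",
    "write_grid",
    "load_config",
    "ConfigError",
    "save_trial_state",
    "load_trial_state",
    "render_oc_table",
    "oc_to_frame",
]

ROW_ORDERS = ("b_desc", "b_asc")


class ConfigError(ValueError):
    """Configuration file failed validation."""


def read_grid(path: str | Path, row_order: str = "b_desc") -> np.ndarray:
    """Read an ``I x J`` grid CSV into the internal (drug A, drug B) layout.

    Blank cells become NaN (used for partially specified median grids).
    """
    if row_order not in ROW_ORDERS:
        raise ConfigError(f"row_order must be one of {ROW_ORDERS}")
    frame = pd.read_csv(path, header=None)
    arr = frame.to_numpy(dtype=float)
    if row_order == "b_desc":
        arr = np.flipud(arr)
    return arr.T.copy()  # rows were drug B, columns drug A


def write_grid(grid: np.ndarray, path: str | Path, row_order: str = "b_desc") -> None:
    if row_order not in ROW_ORDERS:
        raise ConfigError(f"row_order must be one of {ROW_ORDERS}")
    arr = np.asarray(grid, dtype=float).T
    if row_order == "b_desc":
        arr = np.flipud(arr)
    pd.DataFrame(arr).to_csv(path, header=False, index=False)


_OPTION_FIELDS = {
    "theta",
    "epsilon",
    "cohort_size",
    "n_cohorts",
    "strategy",
    "selection",
    "constraint",
    "coherence",
    "start_dose",
    "seed",
}


def load_config(path: str | Path) -> tuple[DesignOptions, PriorSpec | None]:
    """Load a YAML design config, applying and validating defaults.

    Required key: ``theta``.  Optional prior section points at median and
    strength grid CSVs (``median_grid``, ``strength_grid`` or scalar
    ``strength``, ``row_order``).  ``start_dose`` is 1-based in the file.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    if "theta" not in raw:
        raise ConfigError("missing required field: theta")
    opts_raw = {k: raw[k] for k in raw if k in _OPTION_FIELDS}
    if "start_dose" in opts_raw:
        sd = opts_raw["start_dose"]
        if not (isinstance(sd, (list, tuple)) and len(sd) == 2):
            raise ConfigError("start_dose must be a pair of 1-based levels")
        opts_raw["start_dose"] = (int(sd[0]) - 1, int(sd[1]) - 1)
    try:
        options = DesignOptions(**opts_raw)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"invalid design options: {err}") from err

    prior_spec = None
    if "prior" in raw:
        p = raw["prior"]
        row_order = p.get("row_order", "b_desc")
        med = read_grid(path.parent / p["median_grid"], row_order)
        if "strength_grid" in p:
            strength = read_grid(path.parent / p["strength_grid"], row_order)
        elif "strength" in p:
            strength = float(p["strength"])
        else:
            raise ConfigError("prior section needs strength or strength_grid")
        try:
            prior_spec = PriorSpec(medians=med, strength=strength, theta=options.theta)
        except ValueError as err:
            raise ConfigError(f"invalid prior specification: {err}") from err
    return options, prior_spec


@dataclass
class TrialState:
    """Serializable snapshot of a running trial (JSON)."""

    options: DesignOptions
    data: TrialData
    rng_state: dict | None = None


def save_trial_state(state: TrialState, path: str | Path) -> None:
    payload = {
        "options": asdict(state.options),
        "n": state.data.n.tolist(),
        "x": state.data.x.tolist(),
        "history": [
            [m, list(dose), npat, ndlt] for m, dose, npat, ndlt in state.data.history
        ],
        "rng_state": state.rng_state,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_trial_state(path: str | Path) -> TrialState:
    with open(path) as fh:
        payload = json.load(fh)
    opts_raw = dict(payload["options"])
    opts_raw["start_dose"] = tuple(opts_raw["start_dose"])
    options = DesignOptions(**opts_raw)
    data = TrialData(
        n=np.array(payload["n"], dtype=int),
        x=np.array(payload["x"], dtype=int),
        history=[
            (m, (dose[0], dose[1]), npat, ndlt)
            for m, dose, npat, ndlt in payload["history"]
        ],
    )
    return TrialState(options=options, data=data, rng_state=payload.get("rng_state"))


def oc_to_frame(oc: OperatingCharacteristics, style: str = "study1") -> pd.DataFrame:
    """OC summary as a one-row DataFrame in the requested table layout.

    ``study1``: five experimentation bands, five recommendation bands and
    the mean number of recommended doses (11 numeric columns).  ``study2``:
    at-target / within-10 / over-10 / none for recommendation then
    experimentation (8 numeric columns, the experimentation bands rescaled
    to the planned-patient denominator so the row sums to 100).
    """
    if oc.n_trials < 1:
        raise ValueError("operating characteristics from zero trials")
    if style == "study1":
        row: dict[str, float] = {}
        for lab in oc.band_labels:
            row[f"exp {lab}"] = oc.experimentation_pct[lab]
        for lab in oc.band_labels:
            row[f"rec {lab}"] = oc.recommendation_pct[lab]
        row["mean n recommended"] = oc.mean_n_recommended
        return pd.DataFrame([row])
    if style == "study2":
        treated_share = 1.0 - oc.untreated_pct / 100.0
        row = {}
        for lab in oc.band_labels:
            row[f"rec {lab}"] = oc.recommendation_pct[lab]
        row["rec none"] = oc.none_pct
        for lab in oc.band_labels:
            row[f"exp {lab}"] = oc.experimentation_pct[lab] * treated_share
        row["exp none"] = oc.untreated_pct
        return pd.DataFrame([row])
    raise ValueError(f"unknown style {style!r}")


def render_oc_table(oc: OperatingCharacteristics, style: str = "study1") -> str:
    """Plain-text OC table; percentages rounded to integers, mean to 1 d.p."""
    frame = oc_to_frame(oc, style)
    shown = frame.copy()
    for col in shown.columns:
        if col == "mean n recommended":
            shown[col] = shown[col].round(1)
        else:
            shown[col] = shown[col].round(0).astype(int)
    return shown.to_string(index=False)
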