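"""Monte-Carlo construction of non-failing and failing model populations.

Directional regulation in heart failure (from ventricular mRNA expression
data): G_CaL, G_to, G_Kr and J_up trend down, G_NaCa trends up, and G_Ks and
G_K1 show no trend.  The non-failing population samples every scaling
uniformly within +/-30% of baseline; in the failing population down-regulated
parameters are sampled on [0.40, 1.00] of baseline, up-regulated on
[1.00, 1.60], and unregulated parameters keep the non-failing range.
Components are sampled independently (no co-regulation data is available).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scalings import PARAM_NAMES, PARAM_SYMBOLS, ScalingVector

CONDITIONS = ("non-failing", "failing")

_REGULATION = {
    "G_CaL": "down",
    "G_to": "down",
    "G_Kr": "down",
    "J_up": "down",
    "G_NaCa": "up",
    "G_Ks": "none",
    "G_K1": "none",
}

#: sampling interval per regulation direction in the failing population
_HF_BOUNDS = {"down": (0.40, 1.00), "up": (1.00, 1.60), "none": (0.70, 1.30)}
_NF_BOUNDS = (0.70, 1.30)


def regulation_table() -> dict:
    """Direction of heart-failure regulation for each conductance symbol."""
    return dict(_REGULATION)


def regulation_of(symbol: str) -> str:
    try:
        return _REGULATION[symbol]
    except KeyError:
        raise KeyError(
            f"unknown parameter symbol {symbol!r}; expected one of "
            f"{sorted(_REGULATION)}") from None


def default_bounds(condition: str) -> dict:
    """Per-parameter (lower, upper) sampling bounds for a condition."""
    if condition == "non-failing":
        return {p: _NF_BOUNDS for p in PARAM_NAMES}
    if condition == "failing":
        return {p: _HF_BOUNDS[_REGULATION[PARAM_SYMBOLS[p]]] for p in PARAM_NAMES}
    raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of one Monte-Carlo population."""

    condition: str
    n_cells: int
    seed: int
    bounds: dict = field(default_factory=dict)  # optional per-parameter override

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        merged = default_bounds(self.condition)
        merged.update(self.bounds)
        for p, (lo, hi) in merged.items():
            if p not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {p!r} in bounds")
            if lo <= 0 or lo > hi:
                raise ValueError(f"invalid bounds for {p}: ({lo}, {hi})")
        object.__setattr__(self, "bounds", merged)


def sample_population(spec: PopulationSpec) -> list[ScalingVector]:
    """Draw ``spec.n_cells`` scaling vectors, componentwise uniform.

    Reproducible for a given seed: a single named generator drives all
    components in canonical parameter order.
    """
    rng = np.random.default_rng(spec.seed)
    cols = {}
    for p in PARAM_NAMES:
        lo, hi = spec.bounds[p]
        cols[p] = rng.uniform(lo, hi, spec.n_cells)
    return [ScalingVector(**{p: cols[p][i] for p in PARAM_NAMES})
            for i in range(spec.n_cells)]


def population_frame(spec: PopulationSpec) -> pd.DataFrame:
    """Sampled population as a DataFrame (cell index + scaling columns)."""
    vecs = sample_population(spec)
    df = pd.DataFrame([v.to_array() for v in vecs], columns=list(PARAM_NAMES))
    df.insert(0, "cell", np.arange(spec.n_cells))
    df.insert(0, "condition", spec.condition)
    return df


def paired_population_frames(n_cells: int, seed: int) -> pd.DataFrame:
    """Non-failing and failing populations from common uniform draws.

    Cell i of the failing population occupies the same quantile of every
    sampling interval as cell i of the non-failing population, so each
    marginal population is exactly its usual uniform distribution while
    between-condition contrasts (median differences, percent changes) have
    far lower Monte-Carlo variance than with independent sampling.  Returns
    a single frame with both conditions stacked.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    u = {p: rng.uniform(0.0, 1.0, n_cells) for p in PARAM_NAMES}
    frames = []
    for condition in CONDITIONS:
        bounds = default_bounds(condition)
        df = pd.DataFrame({p: bounds[p][0] + (bounds[p][1] - bounds[p][0]) * u[p]
                           for p in PARAM_NAMES})
        df.insert(0, "cell", np.arange(n_cells))
        df.insert(0, "condition", condition)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_population(df: pd.DataFrame, spec: PopulationSpec, csv_path) -> None:
    """Write the population CSV plus a JSON sidecar recording spec and seed."""
    df.to_csv(csv_path, index=False)
    sidecar = str(csv_path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump({"condition": spec.condition, "n_cells": spec.n_cells,
                   "seed": spec.seed,
                   "bounds": {p: list(spec.bounds[p]) for p in PARAM_NAMES}},
                  fh, indent=2)


def read_population(csv_path) -> pd.DataFrame:
    df = pd.read_csv(csv_path)
    missing = set(PARAM_NAMES) - set(df.columns)
    if missing:
        raise ValueError(f"population CSV missing columns {sorted(missing)}")
    return df
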