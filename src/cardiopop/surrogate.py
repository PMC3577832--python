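"""Synthetic trace/biomarker generator with known ground truth.

Produces paired Vm/Cai beat traces whose extracted biomarkers equal
prescribed targets, and population tables in which every biomarker depends
linearly on the conductance scalings with planted effect sizes plus Gaussian
noise.  This lets the biomarker-extraction and regression stages be tested
end-to-end in milliseconds with exact expectations, without ODE solves.

The waveforms are deliberately simple (sinusoidal 2 ms upstroke so the
steepest point is unambiguous, then a piecewise-linear repolarization
anchored at the 30% and 80% recovery times): they are chosen for closed-form
biomarker inversion, not physiological fidelity, and are test scaffolding
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biomarkers import BIOMARKER_NAMES
from .pacing import Trace
from .population import PopulationSpec, sample_population
from .scalings import PARAM_NAMES, ScalingVector

#: baseline biomarker targets near the unscaled endocardial model at 1500 ms
DEFAULT_TARGETS = {
    "APD80": 270.0,     # ms
    "APD3080": 0.66,    # dimensionless
    "CaTD80": 500.0,    # ms
    "CaTD3080": 0.39,   # dimensionless
    "CaTMax": 2.8e-4,   # mM
    "DAPCaT": 11.0,     # ms
}


def default_effects() -> dict:
    """Plausible planted effect sizes (biomarker units per unit scaling).

    Signs mimic the sensitivity structure of the real model: APD is dominated
    by a negative I_Kr effect, CaT durations by negative SERCA/NCX effects.
    Purely illustrative defaults for tests and examples.
    """
    return {
        "APD80": {"s_Kr": -90.0, "s_CaL": 30.0, "s_Ks": -8.0, "s_K1": -6.0},
        "APD3080": {"s_Kr": 0.08, "s_CaL": 0.05},
        "CaTD80": {"s_up": -380.0, "s_NaCa": -120.0, "s_CaL": 60.0},
        "CaTD3080": {"s_up": -0.10, "s_NaCa": -0.05},
        "CaTMax": {"s_CaL": 2.0e-4, "s_up": 1.0e-4},
        "DAPCaT": {"s_up": -9.0, "s_CaL": -3.0, "s_NaCa": -2.0},
    }


@dataclass(frozen=True)
class SurrogateSpec:
    """Ground-truth generating model for surrogate populations."""

    targets: dict = field(default_factory=lambda: dict(DEFAULT_TARGETS))
    effects: dict = field(default_factory=dict)   # biomarker -> {param: slope}
    noise_sd: dict = field(default_factory=dict)  # biomarker -> SD
    seed: int = 0

    def __post_init__(self):
        t = dict(DEFAULT_TARGETS)
        t.update(self.targets)
        object.__setattr__(self, "targets", t)
        _validate_targets(t)
        for bm in list(self.effects) + list(self.noise_sd):
            if bm not in BIOMARKER_NAMES:
                raise ValueError(f"unknown biomarker {bm!r}")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise SDs must be non-negative")

    def biomarker_targets(self, scalings: ScalingVector, rng=None,
                          validate: bool = False) -> dict:
        """Planted linear response for one cell (plus noise when rng given).

        ``validate`` re-checks the (possibly noisy) values against the
        waveform invariants; trace generation requires it, direct table
        generation does not."""
        out = {}
        for bm in BIOMARKER_NAMES:
            val = self.targets[bm]
            for p, slope in self.effects.get(bm, {}).items():
                val += slope * (getattr(scalings, p) - 1.0)
            if rng is not None:
                sd = self.noise_sd.get(bm, 0.0)
                if sd > 0:
                    val += rng.normal(0.0, sd)
            out[bm] = val
        if validate:
            _validate_targets(out)
        return out


def _validate_targets(t: dict) -> None:
    if not 0.0 < t["APD3080"] <= 1.0 or not 0.0 < t["CaTD3080"] <= 1.0:
        raise ValueError("triangulation ratios must lie in (0, 1]")
    if t["APD80"] <= 0 or t["CaTD80"] <= 0:
        raise ValueError("durations must be positive")
    if t["CaTMax"] <= 1.0e-4:
        raise ValueError("CaTMax must exceed the 1e-4 mM diastolic baseline")
    if t["DAPCaT"] < 0:
        raise ValueError("DAPCaT must be non-negative")


def _beat(n, t_up, peak, baseline, d30, d80, tail=30.0):
    """One analytic beat on a 1 ms grid of length n.

    Sinusoidal rise of 2 ms centred at ``t_up`` (steepest slope exactly at
    ``t_up``), then piecewise-linear descent through the 30% and 80% recovery
    levels at ``t_up + d30`` and ``t_up + d80``, reaching baseline ``tail``
    ms later.
    """
    if not 0 < d30 <= d80:
        raise ValueError(f"need 0 < duration30 <= duration80, got {d30}, {d80}")
    if t_up + d80 + tail >= n:
        raise ValueError("beat does not fit in the window")
    t = np.arange(n, dtype=float)
    amp = peak - baseline
    v30 = peak - 0.30 * amp
    v80 = peak - 0.80 * amp
    knots_t = [0.0, t_up - 1.0, t_up + 1.0, t_up + d30, t_up + d80,
               t_up + d80 + tail, float(n)]
    knots_v = [baseline, baseline, peak, v30, v80, baseline, baseline]
    y = np.interp(t, knots_t, knots_v)
    rise = (t >= t_up - 1.0) & (t <= t_up + 1.0)
    y[rise] = baseline + amp * 0.5 * (1.0 + np.sin(0.5 * np.pi * (t[rise] - t_up)))
    return y


def generate_trace_pair(scalings: ScalingVector, spec: SurrogateSpec,
                        bcl: int = 1500, t_up: float = 10.0,
                        alternate_apd80: float = 0.0,
                        alternate_catd80: float = 0.0) -> Trace:
    """Two-beat surrogate trace whose biomarkers equal the spec-implied values.

    ``alternate_*`` offsets are added to the penultimate beat's durations to
    inject beat-to-beat alternation (e.g. 8 ms to trip the alternans rule).
    Noise, when configured, perturbs the per-cell biomarker targets (shared
    by both beats), not the samples.
    """
    bcl = int(bcl)
    rng = np.random.default_rng(spec.seed)
    tgt = spec.biomarker_targets(scalings, rng=rng, validate=True)
    apd80 = tgt["APD80"]
    apd30 = tgt["APD3080"] * apd80
    catd80 = tgt["CaTD80"]
    catd30 = tgt["CaTD3080"] * catd80
    vm = np.empty(2 * bcl)
    cai = np.empty(2 * bcl)
    for b, (dv, dca) in enumerate([(alternate_apd80, alternate_catd80), (0.0, 0.0)]):
        sl = slice(b * bcl, (b + 1) * bcl)
        vm[sl] = _beat(bcl, t_up, 40.0, -85.0, apd30 + dv, apd80 + dv)
        cai[sl] = _beat(bcl, t_up + tgt["DAPCaT"], tgt["CaTMax"], 1.0e-4,
                        catd30 + dca, catd80 + dca, tail=60.0)
    return Trace(time=np.arange(2 * bcl, dtype=float), vm=vm, cai=cai,
                 bcl=bcl, n_beats=2)


def generate_biomarker_table(n_cells: int, condition: str,
                             spec: SurrogateSpec, bcl: int = 1500,
                             seed: int | None = None) -> pd.DataFrame:
    """Directly emit a population biomarker table (no traces).

    Scalings are sampled from the condition's uniform intervals; biomarkers
    follow the planted linear model with Gaussian noise.  The layout is
    byte-compatible with the real pipeline's biomarker CSV.
    """
    seed = spec.seed if seed is None else seed
    pop = sample_population(PopulationSpec(condition, n_cells, seed=seed))
    rng = np.random.default_rng(seed + 1)
    rows = []
    for i, sv in enumerate(pop):
        tgt = spec.biomarker_targets(sv, rng=rng)
        row = {"condition": condition, "cell": i, "bcl": int(bcl)}
        row.update({p: getattr(sv, p) for p in PARAM_NAMES})
        row.update({bm: tgt[bm] for bm in BIOMARKER_NAMES})
        row.update({"APD30": tgt["APD3080"] * tgt["APD80"],
                    "CaTD30": tgt["CaTD3080"] * tgt["CaTD80"],
                    "alternans_V": False, "alternans_Ca": False,
                    "captured": True})
        rows.append(row)
    return pd.DataFrame(rows)
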