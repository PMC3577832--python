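"""The O'Hara-Rudy (ORd) human ventricular endocardial cell model.

Exposes the model as a parameterized stiff ODE system: baseline parameters,
the published initial state, a validated right-hand-side, and per-current
evaluation for analysis.  The heavy numerics live in the compiled kernel
(:mod:`cardiopop._ord_kernel`); this module is the friendly face.

The equation set is the 41-state endocardial formulation of O'Hara, Virag,
Varro & Rudy (2011), with seven scalable maximal conductances/fluxes
(G_Kr, G_Ks, G_K1, G_to, P_CaL, G_NaCa, J_up).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _ord_kernel as _k
from .scalings import PARAM_NAMES, ScalingVector

#: names of the 41 state variables, in state-vector order
STATE_NAMES = (
    "V", "Nai", "Nass", "Ki", "Kss", "Cai", "Cass", "Cansr", "Cajsr",
    "m", "hf", "hs", "j", "hsp", "jp", "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp",
    "d", "ff", "fs", "fcaf", "fcas", "jca", "nca", "ffp", "fcafp",
    "xrf", "xrs", "xs1", "xs2", "xk1",
    "Jrelnp", "Jrelp", "CaMKt",
)

#: published baseline values of the scalable parameters (model-native units)
BASELINE = {
    "G_Kr": 0.046,      # mS/uF
    "G_Ks": 0.0034,     # mS/uF
    "G_K1": 0.1908,     # mS/uF
    "G_to": 0.02,       # mS/uF
    "G_CaL": 0.0001,    # cm/s (L-type channel permeability P_Ca)
    "G_NaCa": 0.0008,   # uA/uF (exchanger turnover scale)
    "J_up": 0.004375,   # mM/ms (SERCA uptake V_max, non-phosphorylated)
}

_SYMBOL_BY_PARAM = {
    "s_Kr": "G_Kr", "s_Ks": "G_Ks", "s_K1": "G_K1", "s_to": "G_to",
    "s_CaL": "G_CaL", "s_NaCa": "G_NaCa", "s_up": "J_up",
}

CURRENT_NAMES = (
    "INa", "INaL", "Ito", "ICaL", "ICaNa", "ICaK", "IKr", "IKs", "IK1",
    "INaCa_i", "INaCa_ss", "INaK", "INab", "ICab", "IKb", "IpCa",
    "Jrel", "Jup", "Jleak", "Jtr", "Jdiff", "CaMKa",
)


@dataclass(frozen=True)
class CellParameters:
    """Scalable parameters of one cell variant (absolute, model-native units).

    All other ORd parameters are held at their published values inside the
    kernel.  ``scalings`` records the multipliers the cell was built from.
    """

    G_Kr: float
    G_Ks: float
    G_K1: float
    G_to: float
    G_CaL: float
    G_NaCa: float
    J_up: float
    scalings: ScalingVector

    def scale_array(self) -> np.ndarray:
        return self.scalings.to_array()


def make_cell(scalings: ScalingVector | dict | None = None) -> CellParameters:
    """Build cell parameters from conductance scalings.

    With all scalings 1.0 the returned parameters equal the published ORd
    endocardial baseline; each scalable parameter is baseline times its
    multiplier.  Non-positive or missing components are rejected with the
    offending component named (validation lives in :class:`ScalingVector`).
    """
    if scalings is None:
        scalings = ScalingVector()
    elif isinstance(scalings, dict):
        scalings = ScalingVector.from_mapping(scalings)
    vals = {
        _SYMBOL_BY_PARAM[p]: BASELINE[_SYMBOL_BY_PARAM[p]] * getattr(scalings, p)
        for p in PARAM_NAMES
    }
    return CellParameters(scalings=scalings, **vals)


def initial_state() -> np.ndarray:
    """Published ORd endocardial initial state (near-steady-state rest)."""
    y = np.zeros(_k.N_STATES)
    y[_k.IV] = -87.0
    y[_k.INAI] = 7.0
    y[_k.INASS] = 7.0
    y[_k.IKI] = 145.0
    y[_k.IKSS] = 145.0
    y[_k.ICAI] = 1.0e-4
    y[_k.ICASS] = 1.0e-4
    y[_k.ICANSR] = 1.2
    y[_k.ICAJSR] = 1.2
    ones = ("hf", "hs", "j", "hsp", "jp", "hL", "hLp", "iF", "iS",
            "iFp", "iSp", "ff", "fs", "fcaf", "fcas", "jca", "ffp",
            "fcafp", "xk1")
    for name in ones:
        y[STATE_NAMES.index(name)] = 1.0
    return y


def _check_state(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.shape != (_k.N_STATES,):
        raise ValueError(
            f"state vector must have length {_k.N_STATES}, got shape {y.shape}"
        )
    if not np.all(np.isfinite(y)):
        bad = [STATE_NAMES[i] for i in np.flatnonzero(~np.isfinite(y))]
        raise ValueError(f"non-finite state entries: {', '.join(bad)}")
    return y


def rhs(state, t: float, params: CellParameters, i_stim: float = 0.0) -> np.ndarray:
    """Time derivative of the full state vector (autonomous; ``t`` unused).

    ``i_stim`` is the applied stimulus current density in uA/uF, added to the
    membrane-potential balance (and booked to K+ for charge conservation).
    """
    y = _check_state(state)
    gss = np.empty(_k.N_STATES)
    gtau = np.empty(_k.N_STATES)
    dy = np.zeros(_k.N_STATES)
    cur = np.empty(_k.N_CURRENTS)
    _k.derivs(y, params.scale_array(), float(i_stim), gss, gtau, dy, cur)
    return dy


def currents(state, params: CellParameters, i_stim: float = 0.0) -> dict:
    """Evaluate all membrane currents and SR fluxes at a fixed state."""
    y = _check_state(state)
    gss = np.empty(_k.N_STATES)
    gtau = np.empty(_k.N_STATES)
    dy = np.zeros(_k.N_STATES)
    cur = np.empty(_k.N_CURRENTS)
    _k.derivs(y, params.scale_array(), float(i_stim), gss, gtau, dy, cur)
    return dict(zip(CURRENT_NAMES, cur))


# --- flat key/value serialization ------------------------------------------

def state_to_text(y) -> str:
    y = _check_state(y)
    return "\n".join(f"{n} = {v:.17g}" for n, v in zip(STATE_NAMES, y)) + "\n"


def state_from_text(text: str) -> np.ndarray:
    vals = _parse_kv(text)
    missing = set(STATE_NAMES) - set(vals)
    if missing:
        raise ValueError(f"missing state variables: {sorted(missing)}")
    return np.array([vals[n] for n in STATE_NAMES])


def params_to_text(params: CellParameters) -> str:
    lines = [f"{sym} = {getattr(params, sym):.17g}" for sym in BASELINE]
    lines += [f"{p} = {getattr(params.scalings, p):.17g}" for p in PARAM_NAMES]
    return "\n".join(lines) + "\n"


def params_from_text(text: str) -> CellParameters:
    vals = _parse_kv(text)
    sv = ScalingVector(**{p: vals[p] for p in PARAM_NAMES})
    return make_cell(sv)


def _parse_kv(text: str) -> dict:
    out = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        out[key.strip()] = float(val)
    return out
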