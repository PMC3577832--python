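"""Conductance scaling vectors: the parameter axis of a model population."""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

#: canonical parameter order used everywhere (CSV columns, design matrices)
PARAM_NAMES = ("s_Kr", "s_Ks", "s_K1", "s_to", "s_CaL", "s_NaCa", "s_up")

#: the conductance symbol each scaling multiplies
PARAM_SYMBOLS = {
    "s_Kr": "G_Kr",
    "s_Ks": "G_Ks",
    "s_K1": "G_K1",
    "s_to": "G_to",
    "s_CaL": "G_CaL",
    "s_NaCa": "G_NaCa",
    "s_up": "J_up",
}


@dataclass(frozen=True)
class ScalingVector:
    """Seven dimensionless multipliers defining one cell-model variant.

    A value of 1.0 leaves the corresponding published maximal
    conductance/flux unchanged; all components must be strictly positive.
    """

    s_Kr: float = 1.0
    s_Ks: float = 1.0
    s_K1: float = 1.0
    s_to: float = 1.0
    s_CaL: float = 1.0
    s_NaCa: float = 1.0
    s_up: float = 1.0

    def __post_init__(self):
        for f in fields(self):
            val = getattr(self, f.name)
            if val is None or not np.isfinite(val):
                raise ValueError(f"scaling component {f.name} is missing or non-finite")
            if val <= 0:
                raise ValueError(
                    f"scaling component {f.name} must be strictly positive, got {val}"
                )

    def to_array(self) -> np.ndarray:
        """Return the scalings in canonical order as a float array."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ScalingVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} scalings, got shape {arr.shape}")
        return cls(**dict(zip(PARAM_NAMES, arr)))

    @classmethod
    def from_mapping(cls, mapping) -> "ScalingVector":
        unknown = set(mapping) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown scaling component(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})
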