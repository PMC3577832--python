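"""Reproducible run configuration.

A :class:`RunConfig` captures everything that determines a pipeline run:
population sizes and seeds per condition, the pacing protocol, solver
settings, biomarker conventions, regression options, and the output
directory.  Configs round-trip losslessly through YAML/JSON and are hashed
so every output row is traceable to (seed, cell index, config hash).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .pacing import DEFAULT_BCLS, PacingProtocol, SolverSettings


@dataclass(frozen=True)
class ConditionSpec:
    n_cells: int
    seed: int

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0 <= self.seed < 2 ** 31:
            raise ValueError("seed must be a non-negative 31-bit integer")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of an end-to-end population run.

    Defaults are the study conditions: each full-scale population holds
    16384 cells paced 100 times at each of the 11 step-protocol BCLs.
    Use :func:`desk_config` for a laptop-scale run.
    """

    populations: dict = field(default_factory=lambda: {
        "non-failing": ConditionSpec(16384, 1001),
        "failing": ConditionSpec(16384, 2001),
    })
    bcls: tuple = DEFAULT_BCLS
    paces_per_bcl: int = 100
    stim_amplitude: float = -80.0
    stim_duration: float = 0.5
    solver: SolverSettings = field(default_factory=SolverSettings)
    beat: str = "final"             # beat used for central biomarker values
    standardize_x: bool = True      # standardize regression predictors
    min_rows_factor: int = 10
    save_traces: bool = False       # persist final-two-beat traces (HDF5)
    output_dir: str = "cardiopop_run"

    def __post_init__(self):
        pops = {}
        for cond, spec in self.populations.items():
            if isinstance(spec, dict):
                spec = ConditionSpec(**spec)
            pops[cond] = spec
        object.__setattr__(self, "populations", pops)
        if isinstance(self.solver, dict):
            object.__setattr__(self, "solver", SolverSettings(**self.solver))
        # validate protocol eagerly so bad configs fail before any compute
        self.protocol()
        if self.beat not in ("final", "mean"):
            raise ValueError("beat must be 'final' or 'mean'")

    def protocol(self) -> PacingProtocol:
        return PacingProtocol(bcl_sequence=self.bcls,
                              paces_per_bcl=self.paces_per_bcl,
                              stim_amplitude=self.stim_amplitude,
                              stim_duration=self.stim_duration)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bcls"] = list(self.bcls)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "bcls" in d:
            d["bcls"] = tuple(d["bcls"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def desk_config(n_cells: int = 200, seed: int = 1001,
                output_dir: str = "cardiopop_run") -> RunConfig:
    """Laptop-scale configuration: 200 cells/condition, 5 representative BCLs."""
    return RunConfig(
        populations={"non-failing": ConditionSpec(n_cells, seed),
                     "failing": ConditionSpec(n_cells, seed + 1000)},
        bcls=(1500, 1000, 600, 350, 300),
        output_dir=output_dir,
    )
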