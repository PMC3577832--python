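"""Pacing protocols and trace recording.

The study protocol paces each cell 100 times at each basic cycle length of a
decreasing step sequence (1500 ... 300 ms), carrying the state continuously
from one rate to the next, and keeps the final two beats per rate sampled on
a 1 ms grid for biomarker extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _ord_kernel as _k
from .ord import CellParameters, initial_state

#: the step-protocol BCL sequence, ms
DEFAULT_BCLS = (1500, 1000, 900, 800, 700, 600, 500, 450, 400, 350, 300)


class SolverError(RuntimeError):
    """Raised when integration of a cell fails (state went non-finite)."""


@dataclass(frozen=True)
class PacingProtocol:
    """Cumulative step pacing protocol."""

    bcl_sequence: tuple = DEFAULT_BCLS
    paces_per_bcl: int = 100
    stim_amplitude: float = -80.0   # uA/uF (= uA/cm^2 at C_m = 1 uF/cm^2)
    stim_duration: float = 0.5      # ms

    def __post_init__(self):
        seq = tuple(int(b) for b in self.bcl_sequence)
        object.__setattr__(self, "bcl_sequence", seq)
        if len(seq) == 0:
            raise ValueError("bcl_sequence must be non-empty")
        if any(b2 >= b1 for b1, b2 in zip(seq, seq[1:])):
            raise ValueError("bcl_sequence must be strictly decreasing")
        if self.paces_per_bcl < 2:
            raise ValueError("paces_per_bcl must be >= 2 (final two beats are analyzed)")
        if self.stim_duration <= 0:
            raise ValueError("stim_duration must be positive")


@dataclass(frozen=True)
class SolverSettings:
    """Integrator configuration.

    ``method='adaptive'`` uses the compiled Rush-Larsen/Euler hybrid with the
    step-size limiters ``dv_max`` (mV change of Vm per step) and ``dt_max``;
    halving them refines the solution.  ``method='bdf'`` uses scipy's BDF at
    (``rtol``, ``atol``) and exists as a slow, independent cross-check.
    """

    method: str = "adaptive"
    dt_max: float = 2.0     # ms
    dv_max: float = 0.5     # mV per step
    dt_min: float = 0.001   # ms
    rtol: float = 1.0e-6
    atol: float = 1.0e-8

    def refined(self, factor: float = 10.0) -> "SolverSettings":
        """Settings with all step limiters tightened by ``factor``."""
        return replace(self, dt_max=self.dt_max / factor,
                       dv_max=self.dv_max / factor,
                       rtol=self.rtol / factor, atol=self.atol / factor)


@dataclass
class Trace:
    """Uniformly sampled (1 ms) paired Vm/Cai time series."""

    time: np.ndarray   # ms
    vm: np.ndarray     # mV
    cai: np.ndarray    # mM
    bcl: int           # ms
    n_beats: int = 2

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.vm = np.asarray(self.vm, dtype=float)
        self.cai = np.asarray(self.cai, dtype=float)
        if not (len(self.time) == len(self.vm) == len(self.cai)):
            raise ValueError("time, vm and cai must have equal length")
        if len(self.time) > 1:
            dt = np.diff(self.time)
            if not np.allclose(dt, dt[0]):
                raise ValueError("trace must be uniformly sampled")
        if not (np.all(np.isfinite(self.vm)) and np.all(np.isfinite(self.cai))):
            raise ValueError("trace contains non-finite samples")

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.time, self.vm, self.cai])
        np.savetxt(path, arr, delimiter=",", header="time_ms,Vm_mV,Cai_mM",
                   comments="", fmt="%.10g")

    @classmethod
    def from_csv(cls, path, bcl: int, n_beats: int = 2) -> "Trace":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(time=arr[:, 0], vm=arr[:, 1], cai=arr[:, 2],
                   bcl=bcl, n_beats=n_beats)


def single_bcl_run(cell: CellParameters, bcl: int, n_paces: int,
                   initial: np.ndarray | None = None,
                   settings: SolverSettings = SolverSettings(),
                   stim_amplitude: float = -80.0, stim_duration: float = 0.5,
                   n_record: int = 2):
    """Pace one cell at a single BCL, recording the last ``n_record`` beats.

    Returns ``(trace, final_state)``.  The state is advanced in place of a
    copy of ``initial`` (defaults to the published initial state).
    """
    if n_paces < n_record:
        raise ValueError("n_paces must be >= n_record")
    bcl = int(bcl)
    y = np.array(initial_state() if initial is None else initial, dtype=float)
    sc = cell.scale_array()
    if settings.method == "adaptive":
        vm, cai, status = _k.paced_run(
            y, bcl, n_paces, sc, stim_amplitude, stim_duration,
            settings.dt_max, settings.dv_max, settings.dt_min, n_record)
        if status != 0:
            raise SolverError(
                f"integration failed at BCL={bcl} ms for scalings "
                f"{cell.scalings}")
    elif settings.method == "bdf":
        vm, cai, y = _bdf_run(y, bcl, n_paces, sc, stim_amplitude,
                              stim_duration, settings, n_record)
    else:
        raise ValueError(f"unknown solver method {settings.method!r}")
    t = np.arange(n_record * bcl, dtype=float)
    return Trace(time=t, vm=vm, cai=cai, bcl=bcl, n_beats=n_record), y


def run_step_protocol(cell: CellParameters,
                      protocol: PacingProtocol = PacingProtocol(),
                      initial: np.ndarray | None = None,
                      settings: SolverSettings = SolverSettings()):
    """Run the cumulative step protocol on one cell.

    Returns ``(traces, final_state)`` where ``traces`` maps each BCL to the
    final-two-beat :class:`Trace` at that rate.  The state is carried
    continuously across the decreasing-BCL sequence.
    """
    y = np.array(initial_state() if initial is None else initial, dtype=float)
    traces = {}
    for bcl in protocol.bcl_sequence:
        trace, y = single_bcl_run(
            cell, bcl, protocol.paces_per_bcl, initial=y, settings=settings,
            stim_amplitude=protocol.stim_amplitude,
            stim_duration=protocol.stim_duration)
        traces[bcl] = trace
    return traces, y


def _bdf_run(y, bcl, n_paces, sc, stim_amp, stim_dur, settings, n_record):
    """Reference integration with scipy's BDF (slow; for cross-checks)."""
    from scipy.integrate import solve_ivp

    gss = np.empty(_k.N_STATES)
    gtau = np.empty(_k.N_STATES)
    cur = np.empty(_k.N_CURRENTS)

    def f(t, yy, istim):
        dy = np.zeros(_k.N_STATES)
        _k.derivs(yy, sc, istim, gss, gtau, dy, cur)
        return dy

    vm = np.empty(n_record * bcl)
    cai = np.empty(n_record * bcl)
    for p in range(n_paces):
        rec = p >= n_paces - n_record
        off = (p - (n_paces - n_record)) * bcl if rec else 0
        if rec:
            vm[off] = y[_k.IV]
            cai[off] = y[_k.ICAI]
        # stimulated segment
        sol = solve_ivp(f, (0.0, stim_dur), y, method="BDF", args=(stim_amp,),
                        rtol=settings.rtol, atol=settings.atol,
                        dense_output=rec, max_step=stim_dur)
        y = sol.y[:, -1]
        # free-running segment
        sol2 = solve_ivp(f, (stim_dur, float(bcl)), y, method="BDF",
                         args=(0.0,), rtol=settings.rtol, atol=settings.atol,
                         dense_output=rec)
        y = sol2.y[:, -1]
        if rec:
            grid = np.arange(1.0, float(bcl))
            yy = np.empty((_k.N_STATES, grid.size))
            m1 = grid < stim_dur
            if m1.any():
                yy[:, m1] = sol.sol(grid[m1])
            yy[:, ~m1] = sol2.sol(grid[~m1])
            vm[off + 1: off + bcl] = yy[_k.IV]
            cai[off + 1: off + bcl] = yy[_k.ICAI]
    return vm, cai, y
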