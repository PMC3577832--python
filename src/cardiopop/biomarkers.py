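"""AP and CaT biomarker extraction from final-two-beat traces.

Six biomarkers are computed per cell per BCL from the last two paced beats:
APD80, APD30 and their ratio APD3080 (AP triangulation); CaTD80, CaTD30 and
CaTD3080 (CaT triangulation); CaTMax (peak cytosolic calcium); and DAPCaT
(delay between AP and CaT upstrokes).  Durations run from the upstroke (time
of maximum first derivative, sub-sample refined) to the first return below
``peak - fraction * amplitude`` after the peak, with linear interpolation
between the 1 ms samples.  Amplitude is measured against the signal value at
stimulus onset of the beat, which is robust to slow diastolic drift.

Alternans is flagged when APD80 (voltage) or CaTD80 (calcium) differs by at
least 5 ms between the penultimate and final beats.  A beat counts as
captured when its peak Vm exceeds 0 mV and its maximum upstroke slope
exceeds 10 mV/ms; cells with a non-captured beat (e.g. 2:1 block at fast
rates) carry NaN biomarkers and are excluded from downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .pacing import Trace

#: beat-to-beat duration difference (ms) at or above which alternans is flagged
ALTERNANS_THRESHOLD_MS = 5.0

#: capture criteria for a voltage beat
CAPTURE_PEAK_MV = 0.0
CAPTURE_SLOPE_MV_PER_MS = 10.0

#: the six biomarkers reported per (cell, BCL)
BIOMARKER_NAMES = ("APD80", "APD3080", "CaTD80", "CaTD3080", "CaTMax", "DAPCaT")


@dataclass
class BiomarkerRecord:
    """Biomarkers plus alternans/capture flags for one cell at one BCL."""

    APD80: float
    APD30: float
    APD3080: float
    CaTD80: float
    CaTD30: float
    CaTD3080: float
    CaTMax: float
    DAPCaT: float
    alternans_V: bool
    alternans_Ca: bool
    captured: bool

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def upstroke_time(signal, window, min_slope: float = 0.0) -> float:
    """Time (ms) of the maximum first derivative of ``signal`` in ``window``.

    ``signal`` is sampled on a 1 ms grid; ``window`` is a ``(start, stop)``
    index pair.  The forward difference locates the steepest rise (ties break
    to the earliest sample); a local quadratic fit through the neighbouring
    slopes refines the estimate below the sample spacing.  Returns NaN when
    the steepest slope does not reach ``min_slope`` (no capture).
    """
    start, stop = window
    seg = np.asarray(signal[start:stop], dtype=float)
    if seg.size < 3:
        raise ValueError("window too short for upstroke detection")
    d = np.diff(seg)
    i = int(np.argmax(d))
    if d[i] < min_slope:
        return np.nan
    # forward difference d[i] sits at t = i + 0.5
    t = i + 0.5
    if 0 < i < d.size - 1:
        denom = d[i - 1] - 2.0 * d[i] + d[i + 1]
        if denom < -1e-12:
            offset = 0.5 * (d[i - 1] - d[i + 1]) / denom
            t += float(np.clip(offset, -0.5, 0.5))
    return float(start) + t


def duration_to_recovery(signal, window, fraction: float,
                         upstroke: float | None = None) -> float:
    """Duration (ms) from the upstroke to ``fraction`` recovery of the peak.

    Amplitude is ``peak - baseline`` with baseline the sample at the window
    start (stimulus onset).  The recovery time is the first crossing of
    ``peak - fraction * amplitude`` after the peak, linearly interpolated.
    Returns NaN when the signal does not recover within the window.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    start, stop = window
    seg = np.asarray(signal[start:stop], dtype=float)
    if upstroke is None:
        upstroke = upstroke_time(signal, window)
    if not np.isfinite(upstroke):
        return np.nan
    baseline = seg[0]
    ipeak = int(np.argmax(seg))
    peak = seg[ipeak]
    thr = peak - fraction * (peak - baseline)
    below = np.flatnonzero(seg[ipeak:] < thr)
    if below.size == 0:
        return np.nan
    j = ipeak + int(below[0])
    if j == 0:
        return np.nan
    # linear interpolation between samples j-1 (>= thr) and j (< thr)
    frac = (seg[j - 1] - thr) / (seg[j - 1] - seg[j])
    t_cross = (j - 1) + frac
    return float(start) + t_cross - upstroke


def detect_alternans(first: float, second: float,
                     threshold: float = ALTERNANS_THRESHOLD_MS) -> bool:
    """Apply the beat-to-beat duration alternans rule (difference >= 5 ms)."""
    if not (np.isfinite(first) and np.isfinite(second)):
        return False
    return bool(abs(second - first) >= threshold)


def _beat_windows(n: int, bcl: int):
    return (0, n // 2), (n // 2, n)


def extract_biomarkers(trace: Trace, bcl: int | None = None,
                       beat: str = "final") -> BiomarkerRecord:
    """Compute the biomarker record from a final-two-beat trace.

    ``beat`` selects the beat used for the central values: ``"final"``
    (default; the penultimate beat then serves only the alternans rule) or
    ``"mean"`` (average of the two beats).
    """
    if beat not in ("final", "mean"):
        raise ValueError("beat must be 'final' or 'mean'")
    bcl = int(trace.bcl if bcl is None else bcl)
    n = len(trace.vm)
    if n != 2 * bcl:
        raise ValueError(
            f"trace length {n} does not match two beats at BCL={bcl} ms")
    win_p, win_f = _beat_windows(n, bcl)

    def beat_values(win):
        vm = trace.vm[win[0]:win[1]]
        up_v = upstroke_time(trace.vm, win, min_slope=CAPTURE_SLOPE_MV_PER_MS)
        cap = np.isfinite(up_v) and vm.max() > CAPTURE_PEAK_MV
        if not cap:
            return dict(cap=False, up_v=np.nan, up_ca=np.nan, apd80=np.nan,
                        apd30=np.nan, catd80=np.nan, catd30=np.nan,
                        catmax=np.nan)
        up_ca = upstroke_time(trace.cai, win)
        apd80 = duration_to_recovery(trace.vm, win, 0.80, upstroke=up_v)
        apd30 = duration_to_recovery(trace.vm, win, 0.30, upstroke=up_v)
        catd80 = duration_to_recovery(trace.cai, win, 0.80, upstroke=up_ca)
        catd30 = duration_to_recovery(trace.cai, win, 0.30, upstroke=up_ca)
        catmax = float(np.max(trace.cai[win[0]:win[1]]))
        return dict(cap=True, up_v=up_v, up_ca=up_ca, apd80=apd80,
                    apd30=apd30, catd80=catd80, catd30=catd30, catmax=catmax)

    p = beat_values(win_p)
    f = beat_values(win_f)
    captured = p["cap"] and f["cap"]
    alternans_v = captured and detect_alternans(p["apd80"], f["apd80"])
    alternans_ca = captured and detect_alternans(p["catd80"], f["catd80"])

    def central(key):
        if not captured:
            return np.nan
        if beat == "final":
            return f[key]
        return 0.5 * (p[key] + f[key])

    apd80 = central("apd80")
    apd30 = central("apd30")
    catd80 = central("catd80")
    catd30 = central("catd30")
    catmax = central("catmax")
    dapcat = (f["up_ca"] - f["up_v"]) if captured else np.nan
    if beat == "mean" and captured:
        dapcat = 0.5 * ((p["up_ca"] - p["up_v"]) + (f["up_ca"] - f["up_v"]))
    with np.errstate(invalid="ignore", divide="ignore"):
        apd3080 = apd30 / apd80 if np.isfinite(apd80) and apd80 > 0 else np.nan
        catd3080 = (catd30 / catd80
                    if np.isfinite(catd80) and catd80 > 0 else np.nan)
    return BiomarkerRecord(
        APD80=apd80, APD30=apd30, APD3080=apd3080,
        CaTD80=catd80, CaTD30=catd30, CaTD3080=catd3080,
        CaTMax=catmax, DAPCaT=dapcat,
        alternans_V=bool(alternans_v), alternans_Ca=bool(alternans_ca),
        captured=bool(captured),
    )
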