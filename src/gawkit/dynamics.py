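"""Glottal-dynamic parameters on the total glottal area waveform.

Within each maximum-based cycle [max_i, max_{i+1}) the minimum of the area
locates the (near-)closed instant.  From these landmarks:

* CQ (closing quotient): closing duration / period — share of the cycle the
  glottis spends closing;
* SQ (speed quotient): opening / closing duration — opening-closing speed
  ratio;
* PQ (plateau quotient): closed-plateau duration / period, with "plateau"
  taken as all samples within a small relative threshold of the cycle
  minimum (default 5% of the cycle's range);
* GGI (glottis gap index): A_min / A_max — residual opening during closure,
  relative to peak area;
* GAI (glottal area index): (mean - min)/(max - min) — normalized mean open
  area of the cycle.

Each parameter is reported as mean and sample standard deviation over
cycles.  CQ, PQ, GGI, GAI lie in [0, 1]; SQ is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cycles import CycleSet
from .errors import DegenerateSignalError, TooFewCyclesError

__all__ = ["PhaseLandmarks", "phase_landmarks", "quotients", "gap_indices"]

#: relative threshold above the cycle minimum that still counts as "closed"
DEFAULT_PLATEAU_EPS = 0.05


@dataclass
class PhaseLandmarks:
    """Per-cycle timing landmarks (all durations in seconds)."""

    periods_s: np.ndarray
    closing_s: np.ndarray   # time from the cycle-start maximum to the minimum
    opening_s: np.ndarray   # time from the minimum to the next maximum
    plateau_s: np.ndarray   # total time spent within plateau_eps of the minimum


def phase_landmarks(signal, cycles: CycleSet, plateau_eps: float = DEFAULT_PLATEAU_EPS) -> PhaseLandmarks:
    """Locate the closed region of each cycle and derive phase durations.

    Requires maximum-based cycles so each interval starts at a maximum.
    The closed region is the set of samples within ``plateau_eps`` of the
    cycle minimum (relative to the cycle's range).  Closing runs from the
    cycle-start maximum to the first closed sample, opening from the last
    closed sample to the next maximum; this keeps a flat closed plateau out
    of both phase durations.  The plateau duration counts all closed
    samples (ties at the minimum resolve to the earliest sample
    automatically, since the whole tied region is inside the band).
    """
    if cycles.basis != "maximum":
        raise ValueError("phase landmarks require maximum-based cycles")
    if cycles.n_cycles < 2:
        raise TooFewCyclesError("need at least 2 complete cycles")
    x = np.asarray(signal, float)
    n = cycles.n_cycles
    periods = np.diff(cycles.boundaries) / cycles.fs
    closing = np.empty(n)
    opening = np.empty(n)
    plateau = np.empty(n)
    dt = 1.0 / cycles.fs
    for i, (a, b) in enumerate(cycles.slices()):
        seg = x[a:b]
        lo, hi = seg.min(), seg.max()
        if hi == lo:
            raise DegenerateSignalError("flat cycle: landmarks undefined")
        closed = np.flatnonzero(seg <= lo + plateau_eps * (hi - lo))
        closing[i] = closed[0] * dt
        opening[i] = (len(seg) - closed[-1]) * dt
        plateau[i] = len(closed) * dt
    return PhaseLandmarks(periods_s=periods, closing_s=closing, opening_s=opening, plateau_s=plateau)


def quotients(landmarks: PhaseLandmarks):
    """(CQ mean, CQ std, SQ mean, SQ std, PQ mean, PQ std).

    Cycles with zero closing duration have no defined speed quotient and are
    skipped for SQ (with a warning); if all cycles are skipped an error is
    raised.
    """
    t = landmarks.periods_s
    cq = landmarks.closing_s / t
    pq = landmarks.plateau_s / t
    ok = landmarks.closing_s > 0
    if not np.all(ok):
        warnings.warn("cycles with zero closing duration skipped for SQ", stacklevel=2)
    if not np.any(ok):
        raise DegenerateSignalError("no cycle with positive closing duration")
    sq = landmarks.opening_s[ok] / landmarks.closing_s[ok]
    return (
        float(cq.mean()), float(cq.std(ddof=1)),
        float(sq.mean()), float(sq.std(ddof=1)) if len(sq) > 1 else 0.0,
        float(pq.mean()), float(pq.std(ddof=1)),
    )


def gap_indices(signal, cycles: CycleSet):
    """(GGI mean, GGI std, GAI mean, GAI std)."""
    if cycles.n_cycles < 2:
        raise TooFewCyclesError("need at least 2 complete cycles")
    x = np.asarray(signal, float)
    ggi, gai = [], []
    for a, b in cycles.slices():
        seg = x[a:b]
        lo, hi = seg.min(), seg.max()
        if hi <= lo:
            raise DegenerateSignalError("flat cycle: gap indices undefined")
        if hi <= 0:
            raise DegenerateSignalError("non-positive cycle maximum: GGI undefined")
        ggi.append(max(lo, 0.0) / hi)
        gai.append((seg.mean() - lo) / (hi - lo))
    ggi, gai = np.asarray(ggi), np.asarray(gai)
    return (
        float(ggi.mean()), float(ggi.std(ddof=1)),
        float(gai.mean()), float(gai.std(ddof=1)),
    )
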