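"""Left/right vocal-fold symmetry parameters from GAW_L and GAW_R.

The glottal area is split at the glottal midline into a left and a right
half whose waveforms would be identical for perfectly symmetric vocal-fold
oscillation.  Four families of per-cycle measures quantify departures:

* phase: PhA_i = (t_peak,L - t_peak,R) / T_i (signed relative peak delay;
  computed on minimum-based cycles so each cycle contains one full peak),
  PhAI_i = |PhA_i|;
* amplitude: AmSI_i = min(a_L, a_R)/max(a_L, a_R), AmS_i = (a_R - a_L)/(a_R + a_L)
  with a the per-cycle peak-to-peak amplitudes;
* spatial: as amplitude but on the cycle-integrated areas;
* waveform: WaSI_i = Pearson correlation of the two within-cycle waveforms.

Sign convention: positive signed values mean the right half leads (phase) or
is larger (amplitude/spatial).  All *SI indices lie in (0, 1]; WaSI in
[-1, 1].  Ten scalars are emitted: PhA [Mean], PhAI [Mean], PhAI [Std],
AmS [Mean], AmSI [Mean], AmSI [Std], SpS [Mean], SpSI [Mean], SpSI [Std]
and WaSI [Mean].
"""

from __future__ import annotations

import numpy as np

from .cycles import CycleSet
from .errors import DegenerateSignalError

__all__ = [
    "phase_asymmetry",
    "amplitude_symmetry",
    "spatial_symmetry",
    "waveform_symmetry",
]


def _check_cycles(cycles: CycleSet, n_min: int = 2) -> None:
    if cycles.n_cycles < n_min:
        raise DegenerateSignalError(f"need at least {n_min} complete cycles")


def phase_asymmetry(left, right, min_cycles: CycleSet):
    """(PhA [Mean], PhAI [Mean], PhAI [Std]) from minimum-based cycles."""
    _check_cycles(min_cycles)
    left = np.asarray(left, float)
    right = np.asarray(right, float)
    pha = []
    for a, b in min_cycles.slices():
        seg_l, seg_r = left[a:b], right[a:b]
        if seg_l.max() == seg_l.min() or seg_r.max() == seg_r.min():
            raise DegenerateSignalError("flat half-signal within a cycle: no peak")
        t_l = int(np.argmax(seg_l))
        t_r = int(np.argmax(seg_r))
        pha.append((t_l - t_r) / (b - a))
    pha = np.asarray(pha)
    phai = np.abs(pha)
    return float(pha.mean()), float(phai.mean()), float(phai.std(ddof=1))


def amplitude_symmetry(left, right, cycles: CycleSet):
    """(AmS [Mean], AmSI [Mean], AmSI [Std]) from peak-to-peak amplitudes."""
    _check_cycles(cycles)
    left = np.asarray(left, float)
    right = np.asarray(right, float)
    ams, amsi = [], []
    for a, b in cycles.slices():
        a_l = left[a:b].max() - left[a:b].min()
        a_r = right[a:b].max() - right[a:b].min()
        if a_l <= 0 or a_r <= 0:
            raise DegenerateSignalError("zero amplitude on one half")
        ams.append((a_r - a_l) / (a_r + a_l))
        amsi.append(min(a_l, a_r) / max(a_l, a_r))
    ams, amsi = np.asarray(ams), np.asarray(amsi)
    return float(ams.mean()), float(amsi.mean()), float(amsi.std(ddof=1))


def spatial_symmetry(left, right, cycles: CycleSet):
    """(SpS [Mean], SpSI [Mean], SpSI [Std]) from cycle-integrated areas."""
    _check_cycles(cycles)
    left = np.asarray(left, float)
    right = np.asarray(right, float)
    dt = 1.0 / cycles.fs
    sps, spsi = [], []
    for a, b in cycles.slices():
        s_l = left[a:b].sum() * dt
        s_r = right[a:b].sum() * dt
        if s_l <= 0 or s_r <= 0:
            raise DegenerateSignalError("non-positive integrated area on one half")
        sps.append((s_r - s_l) / (s_r + s_l))
        spsi.append(min(s_l, s_r) / max(s_l, s_r))
    sps, spsi = np.asarray(sps), np.asarray(spsi)
    return float(sps.mean()), float(spsi.mean()), float(spsi.std(ddof=1))


def waveform_symmetry(left, right, cycles: CycleSet) -> float:
    """WaSI [Mean]: mean per-cycle Pearson correlation of the two halves.

    Cycles where either half is constant carry no waveform information and
    are skipped; if all cycles are skipped the signal is degenerate.
    """
    _check_cycles(cycles)
    left = np.asarray(left, float)
    right = np.asarray(right, float)
    vals = []
    for a, b in cycles.slices():
        seg_l, seg_r = left[a:b], right[a:b]
        if seg_l.std() == 0 or seg_r.std() == 0:
            continue
        vals.append(float(np.corrcoef(seg_l, seg_r)[0, 1]))
    if not vals:
        raise DegenerateSignalError("all cycles constant on one half")
    return float(np.mean(vals))
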